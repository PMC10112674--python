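"""Respondent records: CSV schema, skip-logic classification, covariate coding.

The survey reaches three overlapping populations; each respondent is
assigned to exactly one analysis group by a fixed skip-logic priority,
smallest expected population first:

    leases any equid            -> leaser
    else boards any equid       -> boarder
    else keeps equids at home   -> owner

Covariates are coded as 0/1 indicators (region South per the 16-state
Census definition, household income above $75,000, age under 35, COVID
financial-stability categories, sell/stop-lease intent, disciplines,
equid-count bins with 5-9/10-19/20+ collapsed to "5+"), plus current
monthly cost in raw dollars.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ClassificationError, DataError

logger = logging.getLogger(__name__)

COUNT_BINS = ("0", "1", "2-4", "5-9", "10-19", "20+")
_POSITIVE_BINS = set(COUNT_BINS) - {"0"}
_FIVE_PLUS_BINS = {"5-9", "10-19", "20+"}

INCOME_BRACKETS = ("0-25k", "25-50k", "50-75k", "75-100k", "100-150k", ">150k")
HIGH_INCOME_BRACKETS = {"75-100k", "100-150k", ">150k"}
AGE_BRACKETS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84")
YOUNG_AGE_BRACKETS = {"18-24", "25-34"}

#: The 16 Census-South states (two-letter postal codes).
SOUTH_STATES = {
    "AL", "AR", "DE", "FL", "GA", "KY", "LA", "MD",
    "MS", "NC", "OK", "SC", "TN", "TX", "VA", "WV",
}
_STATE_NAMES = {
    "alabama": "AL", "arkansas": "AR", "delaware": "DE", "florida": "FL",
    "georgia": "GA", "kentucky": "KY", "louisiana": "LA", "maryland": "MD",
    "mississippi": "MS", "north carolina": "NC", "oklahoma": "OK",
    "south carolina": "SC", "tennessee": "TN", "texas": "TX",
    "virginia": "VA", "west virginia": "WV",
}

GROUPS = ("owner", "boarder", "leaser")

ARRANGEMENT_TYPES = ("free", "partial", "full", "other", "none")
DISCIPLINES = ("sport", "ranch_western", "other")


@dataclass
class RespondentRecord:
    """One survey row; ``None`` marks a missing answer."""

    id: str
    owns_at_home_count: str = "0"
    boards_count: str = "0"
    leases_count: str = "0"
    current_cost: Optional[float] = None
    lease_type: str = "none"
    board_type: str = "none"
    lease_type_text: str = ""
    board_type_text: str = ""
    disciplines: frozenset = frozenset()
    covid_stability: Optional[str] = None   # less | same | more
    sell_or_stop_intent: Optional[str] = None  # yes | maybe | no
    state: Optional[str] = None
    region: Optional[str] = None            # south | other
    income_bracket: Optional[str] = None
    age_bracket: Optional[str] = None
    sex: Optional[str] = None
    response1: Optional[str] = None         # yes | no
    response2: Optional[str] = None
    followup_frac: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("owns_at_home_count", "boards_count", "leases_count"):
            v = getattr(self, name)
            if v is not None and v not in COUNT_BINS:
                raise DataError(f"{name}={v!r} not a legal count bin {COUNT_BINS}")
        if self.current_cost is not None and self.current_cost < 0:
            raise DataError(f"current_cost must be >= 0, got {self.current_cost}")


def classify_respondent(record: RespondentRecord) -> str:
    """Assign the analysis group by the fixed priority leaser > boarder > owner."""
    if record.leases_count in _POSITIVE_BINS:
        return "leaser"
    if record.boards_count in _POSITIVE_BINS:
        return "boarder"
    if record.owns_at_home_count in _POSITIVE_BINS:
        return "owner"
    raise ClassificationError(
        f"record {record.id!r}: no owned, boarded, or leased equids reported"
    )


# keyword rules for binning free-text "other" lease/board descriptions into
# the three defined tiers; first match wins, no match stays "other"
DEFAULT_BIN_RULES: tuple[tuple[str, str], ...] = (
    (r"no cost|no charge|\bfree\b|don'?t pay|nothing", "free"),
    (r"sole use|all cost|everything|\bfull\b|entire", "full"),
    (r"some cost|shared?\b|\bsplit\b|\bpartial\b|\bhalf\b", "partial"),
)


def bin_other_type(free_text: str, rules: Sequence[tuple[str, str]] = DEFAULT_BIN_RULES) -> str:
    """Bin a free-text "other" lease/board description into a defined tier.

    Returns ``free``/``partial``/``full`` on a keyword match, else
    ``unresolvable`` (the record keeps type "other" and contributes 0 to
    both the Partial and Full indicators).
    """
    text = (free_text or "").lower()
    for pattern, category in rules:
        if re.search(pattern, text):
            return category
    return "unresolvable"


def resolve_arrangement(declared: str, free_text: str,
                        rules: Sequence[tuple[str, str]] = DEFAULT_BIN_RULES) -> str:
    """Effective lease/board type after free-text binning of "other"."""
    if declared != "other":
        return declared
    binned = bin_other_type(free_text, rules)
    return "other" if binned == "unresolvable" else binned


def region_from_state(state: Optional[str]) -> Optional[str]:
    if state is None or str(state).strip() == "":
        return None
    s = str(state).strip()
    code = _STATE_NAMES.get(s.lower(), s.upper())
    return "south" if code in SOUTH_STATES else "other"


#: Model covariates per group, matching the three reported model layouts.
MODEL_COLUMNS = {
    "owner": [
        "current_cost", "own_lease_2_4", "own_lease_5plus",
        "sport", "ranch_western", "other_disc",
        "covid_less_stable", "covid_more_stable",
        "sell_yes", "sell_maybe",
        "south", "ahi_gt_75k", "age_lt_35",
    ],
    "boarder": [
        "current_cost", "own_lease_2_4", "own_lease_5plus",
        "partial", "full",
        "sport", "ranch_western", "other_disc",
        "covid_less_stable", "covid_more_stable",
        "sell_yes", "sell_maybe",
        "south", "ahi_gt_75k", "age_lt_35",
    ],
    "leaser": [
        "current_cost", "own_lease_2_4", "own_lease_5plus",
        "leaser_who_owns", "partial", "full",
        "covid_less_stable", "covid_more_stable",
        "sell_yes", "sell_maybe",
        "south", "ahi_gt_75k", "age_lt_35",
    ],
}


def _count_indicators(bin_value: Optional[str]) -> tuple[Optional[float], Optional[float]]:
    """Collapse the survey count bins into (2-4, 5+) indicators."""
    if bin_value is None:
        return None, None
    return float(bin_value == "2-4"), float(bin_value in _FIVE_PLUS_BINS)


def encode_covariates(record: RespondentRecord, group: str,
                      rules: Sequence[tuple[str, str]] = DEFAULT_BIN_RULES) -> dict:
    """Code one classified record into the model covariate dictionary.

    Missing source answers propagate as ``None`` so listwise filtering
    can drop the record later; indicators are 0/1 floats otherwise.
    """
    if group not in GROUPS:
        raise DataError(f"unknown group {group!r}")
    defining = {"owner": record.owns_at_home_count,
                "boarder": record.boards_count,
                "leaser": record.leases_count}[group]
    c24, c5p = _count_indicators(defining)

    arrangement = "none"
    if group == "boarder":
        arrangement = resolve_arrangement(record.board_type, record.board_type_text, rules)
    elif group == "leaser":
        arrangement = resolve_arrangement(record.lease_type, record.lease_type_text, rules)

    region = record.region if record.region in ("south", "other") else region_from_state(record.state)

    cov = {
        "const": 1.0,
        "current_cost": record.current_cost,
        "own_lease_2_4": c24,
        "own_lease_5plus": c5p,
        "leaser_who_owns": float(
            record.owns_at_home_count in _POSITIVE_BINS
            or record.boards_count in _POSITIVE_BINS
        ),
        "partial": float(arrangement == "partial"),
        "full": float(arrangement == "full"),
        "sport": float("sport" in record.disciplines),
        "ranch_western": float("ranch_western" in record.disciplines),
        "other_disc": float("other" in record.disciplines),
        "covid_less_stable": None if record.covid_stability is None
        else float(record.covid_stability == "less"),
        "covid_more_stable": None if record.covid_stability is None
        else float(record.covid_stability == "more"),
        "sell_yes": None if record.sell_or_stop_intent is None
        else float(record.sell_or_stop_intent == "yes"),
        "sell_maybe": None if record.sell_or_stop_intent is None
        else float(record.sell_or_stop_intent == "maybe"),
        "south": None if region is None else float(region == "south"),
        "ahi_gt_75k": None if record.income_bracket is None
        else float(record.income_bracket in HIGH_INCOME_BRACKETS),
        "age_lt_35": None if record.age_bracket is None
        else float(record.age_bracket in YOUNG_AGE_BRACKETS),
    }
    return cov


def build_model_frame(records: Iterable[RespondentRecord], group: str,
                      rules: Sequence[tuple[str, str]] = DEFAULT_BIN_RULES) -> pd.DataFrame:
    """Classify records, keep the requested group, and encode covariates.

    Returns one row per group member with the model covariates plus the
    raw responses and follow-up fraction; unclassifiable records are
    excluded and logged.
    """
    rows = []
    n_unclassified = 0
    for rec in records:
        try:
            g = classify_respondent(rec)
        except ClassificationError:
            n_unclassified += 1
            continue
        if g != group:
            continue
        cov = encode_covariates(rec, group, rules)
        cov.update(
            id=rec.id,
            response1=rec.response1,
            response2=rec.response2,
            followup_frac=rec.followup_frac,
        )
        rows.append(cov)
    if n_unclassified:
        logger.info("excluded %d unclassifiable records", n_unclassified)
    columns = ["id", "const"] + MODEL_COLUMNS[group] + [
        "response1", "response2", "followup_frac"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def listwise_filter(frame: pd.DataFrame, model_columns: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Keep only rows with every model covariate and both responses present.

    Returns the retained frame and a per-field count of rows that were
    missing that field (a row can be counted under several fields).
    """
    required = list(model_columns) + ["response1", "response2", "followup_frac"]
    drop_log: dict[str, int] = {}
    mask = pd.Series(True, index=frame.index)
    for col in required:
        missing = frame[col].isna()
        if missing.any():
            drop_log[col] = int(missing.sum())
        mask &= ~missing
    kept = frame[mask].copy()
    if drop_log:
        logger.info("listwise deletion dropped %d of %d rows: %s",
                    len(frame) - len(kept), len(frame), drop_log)
    if len(frame) and kept.empty:
        raise DataError("listwise deletion removed every record; model cannot be estimated")
    return kept, drop_log


# ---------------------------------------------------------------------------
# CSV schema

_LIST_SEP = ";"

CSV_COLUMNS = [f.name for f in fields(RespondentRecord)]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, frozenset):
        return _LIST_SEP.join(sorted(value))
    return str(value)


def write_respondents(records: Iterable[RespondentRecord], path) -> None:
    """Write records to the documented UTF-8 CSV schema (empty cell = missing)."""
    rows = []
    for rec in records:
        row = {name: _cell(getattr(rec, name)) for name in CSV_COLUMNS}
        if rec.current_cost is not None:
            row["current_cost"] = f"{rec.current_cost:.2f}"
        if rec.followup_frac is not None:
            row["followup_frac"] = f"{rec.followup_frac:.2f}"
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_respondents(path) -> list[RespondentRecord]:
    """Read respondent records from the documented CSV schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataError(f"CSV missing required columns: {sorted(missing_cols)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in CSV_COLUMNS:
            raw = row[name].strip()
            if raw == "":
                kwargs[name] = None
            elif name in ("current_cost", "followup_frac"):
                kwargs[name] = float(raw)
            elif name == "disciplines":
                kwargs[name] = frozenset(raw.split(_LIST_SEP))
            else:
                kwargs[name] = raw
        if kwargs["id"] is None:
            raise DataError("CSV row without an id")
        if kwargs["disciplines"] is None:
            kwargs["disciplines"] = frozenset()
        for cnt in ("owns_at_home_count", "boards_count", "leases_count"):
            if kwargs[cnt] is None:
                kwargs[cnt] = "0"
        for t in ("lease_type", "board_type"):
            if kwargs[t] is None:
                kwargs[t] = "none"
        for txt in ("lease_type_text", "board_type_text"):
            if kwargs[txt] is None:
                kwargs[txt] = ""
        records.append(RespondentRecord(**kwargs))
    return records
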