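"""Double-bounded bid design and response-to-interval mapping.

Every respondent first faces a bid equal to a 10% increase over their
current monthly cost of care.  A "yes" is followed by a random bid of
11-20% (integer percents, both endpoints inclusive); a "no" by a random
bid of 1-9%.  The two yes/no answers bracket the latent willingness to
pay (WTP), expressed throughout as a *fraction of current cost*:

    yes, yes  ->  [c2y, +inf)      right-censored
    yes, no   ->  [0.10, c2y)      interval
    no,  yes  ->  [c2n, 0.10)      interval
    no,  no   ->  (-inf, c2n)      left-censored

Intervals follow the closed-lower / open-upper convention
``lower <= WTP < upper``; the Gaussian likelihood is insensitive to
boundary openness.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DataError

#: First-bid fraction shown to every respondent.
C1_FRAC = 0.10
#: Legal follow-up fractions after a "yes" (integer percents 11..20).
C2Y_FRACS = tuple(i / 100 for i in range(11, 21))
#: Legal follow-up fractions after a "no" (integer percents 1..9).
C2N_FRACS = tuple(i / 100 for i in range(1, 10))

_FRAC_TOL = 1e-9


@dataclass(frozen=True)
class BidSchedule:
    """One respondent's realized bid fractions.

    ``c2y_frac``/``c2n_frac`` are both drawn up front; the respondent
    only ever sees the one matching their first answer.
    """

    c2y_frac: float
    c2n_frac: float
    c1_frac: float = C1_FRAC

    def __post_init__(self) -> None:
        if not (self.c2n_frac < self.c1_frac < self.c2y_frac):
            raise DataError(
                f"bid schedule must satisfy c2n < c1 < c2y, got "
                f"({self.c2n_frac}, {self.c1_frac}, {self.c2y_frac})"
            )


@dataclass(frozen=True)
class WTPInterval:
    """Censored WTP interval in proportion-of-current-cost units.

    ``censoring`` is one of ``interval`` (both bounds finite), ``left``
    (only an upper bound) or ``right`` (only a lower bound).
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DataError(f"interval requires lower < upper, got [{self.lower}, {self.upper})")
        if math.isinf(self.lower) and math.isinf(self.upper):
            # legal object (used to probe unidentified likelihoods) but never
            # produced by the response mapping
            pass

    @property
    def censoring(self) -> str:
        if math.isinf(self.lower) and math.isinf(self.upper):
            return "unbounded"
        if math.isinf(self.lower):
            return "left"
        if math.isinf(self.upper):
            return "right"
        return "interval"


@dataclass(frozen=True)
class DollarInterval:
    """A WTP interval rescaled to additional USD/month."""

    lower: float
    upper: float
    censoring: str
    degenerate: bool = False


def first_bid_dollars(current_cost: float) -> float:
    """Dollar amount of the first bid: a 10% increase over current cost.

    The amount shown to a respondent is rounded half-up to cents; the
    analysis itself always works with the exact fraction 0.10.
    """
    if current_cost < 0:
        raise DataError(f"current cost must be >= 0, got {current_cost}")
    if current_cost == 0:
        warnings.warn("zero current cost gives a degenerate $0 bid", stacklevel=2)
        return 0.0
    amount = Decimal(str(current_cost)) * Decimal("1.10")
    return float(amount.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def draw_followup(response1: str, rng: np.random.Generator) -> float:
    """Draw the follow-up bid fraction given the first answer.

    Discrete uniform over integer percents: 11-20% after a yes,
    1-9% after a no (both endpoints inclusive).
    """
    if response1 == "yes":
        return int(rng.integers(11, 21)) / 100
    if response1 == "no":
        return int(rng.integers(1, 10)) / 100
    raise DataError(f"response1 must be 'yes' or 'no', got {response1!r}")


def draw_schedule(rng: np.random.Generator) -> BidSchedule:
    """Draw a full schedule (both potential follow-ups) for one respondent."""
    c2y = int(rng.integers(11, 21)) / 100
    c2n = int(rng.integers(1, 10)) / 100
    return BidSchedule(c2y_frac=c2y, c2n_frac=c2n)


def _check_followup(response1: str, frac: float) -> None:
    legal = C2Y_FRACS if response1 == "yes" else C2N_FRACS
    if not any(abs(frac - f) <= _FRAC_TOL for f in legal):
        raise DataError(
            f"follow-up fraction {frac} inconsistent with response1={response1!r}"
        )


def map_to_interval(response1: str, response2: str, followup_frac: float) -> WTPInterval:
    """Map a (response1, response2, follow-up bid) triple to a WTP interval."""
    for r in (response1, response2):
        if r not in ("yes", "no"):
            raise DataError(f"responses must be 'yes'/'no', got {r!r}")
    _check_followup(response1, followup_frac)
    if response1 == "yes":
        if response2 == "yes":
            return WTPInterval(lower=followup_frac, upper=math.inf)
        return WTPInterval(lower=C1_FRAC, upper=followup_frac)
    if response2 == "yes":
        return WTPInterval(lower=followup_frac, upper=C1_FRAC)
    return WTPInterval(lower=-math.inf, upper=followup_frac)


def interval_in_dollars(interval: WTPInterval, current_cost: float) -> DollarInterval:
    """Rescale a fractional interval to additional USD/month at a given cost.

    A zero cost makes every bid $0, so the dollar interval is degenerate
    and flagged as such rather than raised.
    """
    if current_cost < 0:
        raise DataError(f"current cost must be >= 0, got {current_cost}")
    if current_cost == 0:
        return DollarInterval(0.0, 0.0, interval.censoring, degenerate=True)
    return DollarInterval(
        lower=interval.lower * current_cost,
        upper=interval.upper * current_cost,
        censoring=interval.censoring,
    )
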