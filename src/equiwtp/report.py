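"""Headline quantities: mean WTP at covariate means, marginal effects, tables.

The mean WTP for a group is the linear prediction x̄'β̂ at the
estimation-sample covariate means, with a delta-method standard error
sqrt(x̄' V x̄) treating the means as fixed constants (V = robust
coefficient covariance).  Marginal effects are exact in the linear
latent model: a change ``delta`` in covariate j moves predicted WTP by
β̂_j · delta (in fraction-of-current-cost units).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .mle import EstimationDataset, FitResult


@dataclass(frozen=True)
class WTPEstimate:
    """Mean WTP as a fraction of current cost, with delta-method uncertainty."""

    point: float
    se: float
    z: float
    p: float
    covariate_means: np.ndarray


def wtp_at_means(fit: FitResult, data: EstimationDataset,
                 include_mean_variance: bool = False) -> WTPEstimate:
    """Linear prediction of WTP at the estimation-sample covariate means.

    ``include_mean_variance`` adds the sampling variance of the means
    themselves, beta' Cov(x̄) beta, as a sensitivity option; the default
    treats x̄ as fixed.
    """
    xbar = data.covariate_means()
    if xbar.shape[0] != len(fit.names):
        raise DataError("fit and dataset have different covariate layouts")
    point = float(xbar @ fit.beta)
    var = float(xbar @ fit.beta_cov() @ xbar)
    if include_mean_variance:
        cov_xbar = np.cov(data.X, rowvar=False, ddof=1) / data.n
        cov_xbar = np.atleast_2d(cov_xbar)
        var += float(fit.beta @ cov_xbar @ fit.beta)
    se = float(np.sqrt(max(var, 0.0)))
    z = point / se if se > 0 else np.inf * np.sign(point)
    p = float(2 * stats.norm.sf(abs(z)))
    return WTPEstimate(point=point, se=se, z=float(z), p=p, covariate_means=xbar)


def marginal_effect(fit: FitResult, covariate_name: str, delta: float) -> float:
    """Change in predicted WTP fraction for a ``delta`` change in a covariate."""
    if covariate_name not in fit.names:
        raise DataError(f"unknown covariate {covariate_name!r}; have {fit.names}")
    return fit.coef(covariate_name) * delta


def stars(p: float) -> str:
    """Significance stars: *** p<=0.01, ** p<=0.05, * p<=0.10 (<= at each boundary)."""
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


# display labels in the reported-table layout
_ROW_LABELS = {
    "current_cost": "Current care costs",
    "own_lease_2_4": "Own/lease 2 to 4",
    "own_lease_5plus": "Own/lease 5+",
    "leaser_who_owns": "Leaser who owns",
    "partial": "Partial board or lease",
    "full": "Full board or lease",
    "sport": "Sport disciplines",
    "ranch_western": "Ranch/western related disciplines",
    "other_disc": "Other disciplines",
    "covid_less_stable": "COVID impact: Less stable",
    "covid_more_stable": "COVID impact: More stable",
    "sell_yes": "Sell/stop lease post COVID: Yes",
    "sell_maybe": "Sell/stop lease post COVID: Maybe",
    "south": "South",
    "ahi_gt_75k": "Annual household income > $75,000",
    "age_lt_35": "Age: Younger than 35",
    "const": "Constant",
}
_ROW_ORDER = [k for k in _ROW_LABELS if k != "const"] + ["const"]


def _fmt(x: float, digits: int = 4) -> str:
    return f"{x:.{digits}f}"


def format_results_table(fits: Sequence[tuple[str, FitResult, Optional[WTPEstimate]]],
                         fmt: str = "tsv", show_stars: bool = True,
                         digits: int = 4) -> str:
    """Render per-model columns of coefficient (robust SE) plus the footer rows.

    ``fits`` is a sequence of (model name, FitResult, WTPEstimate or
    None); models with disjoint covariate sets share one row list, blank
    where a covariate is absent.  Formats: ``tsv`` or ``markdown``.
    """
    if fmt not in ("tsv", "markdown"):
        raise DataError(f"unknown table format {fmt!r}")
    header = [""]
    for name, _, _ in fits:
        header += [f"{name} coef.", f"{name} SE"]

    present = set()
    for _, fr, _ in fits:
        present.update(fr.names)
    rows = []
    for key in _ROW_ORDER:
        if key not in present:
            continue
        cells = [_ROW_LABELS[key]]
        for _, fr, _ in fits:
            if key in fr.names:
                j = fr.names.index(key)
                se = fr.robust_se()[j]
                p = fr.p_values()[j]
                star = stars(p) if show_stars else ""
                cells += [_fmt(fr.beta[j], digits) + star, _fmt(se, digits)]
            else:
                cells += ["", ""]
        rows.append(cells)

    def footer(label, values):
        cells = [label]
        for v in values:
            cells += v
        rows.append(cells)

    if fits:
        footer("Ln(Sigma)", [
            [_fmt(fr.ln_sigma, digits) + (stars(fr.p_values()[-1]) if show_stars else ""),
             _fmt(fr.robust_se()[-1], digits)] for _, fr, _ in fits])
        footer("Willingness to pay", [
            ["", ""] if est is None else
            [_fmt(est.point, digits) + (stars(est.p) if show_stars else ""), _fmt(est.se, digits)]
            for _, _, est in fits])
        footer("Wald chi2", [
            [_fmt(fr.wald_chi2, 2) + (stars(fr.wald_p) if show_stars else ""), ""]
            for _, fr, _ in fits])
        footer("Observations", [[str(fr.n), ""] for _, fr, _ in fits])

    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    width = len(header)
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * width) + "|"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines) + "\n"


def fit_to_json(fit: FitResult, estimate: Optional[WTPEstimate] = None,
                reference_cost: Optional[float] = None) -> str:
    """Serialize a fit (and optionally its mean-WTP prediction) to JSON.

    Coefficients are emitted at full precision — never rounded below
    their significant digits.  ``reference_cost`` converts the WTP
    fraction to additional dollars/month at that monthly cost.
    """
    payload = fit.to_dict()
    payload["stars"] = {name: stars(fit.p_values()[j])
                        for j, name in enumerate(fit.names)}
    if estimate is not None:
        payload["wtp_at_means"] = {
            "fraction": estimate.point, "robust_se": estimate.se,
            "z": estimate.z, "p": estimate.p,
        }
        if reference_cost is not None:
            payload["wtp_at_means"]["dollars_per_month_at_reference_cost"] = (
                estimate.point * reference_cost)
            payload["wtp_at_means"]["reference_cost"] = reference_cost
    return json.dumps(payload, indent=2, sort_keys=False)
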