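"""Descriptive layer: summary rows, response-sequence proportions, t-tests."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


def summarize(values: Iterable[float], variable: str = "") -> SummaryRow:
    """Sample mean, SD (n-1 denominator), min, max.

    A single observation has no sample SD; it is reported as 0 with a
    warning rather than NaN.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise DataError(f"cannot summarize empty group for {variable!r}")
    if x.size == 1:
        warnings.warn(f"{variable or 'variable'}: n=1, sample SD undefined, reporting 0",
                      stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=1))
    return SummaryRow(variable=variable, n=int(x.size), mean=float(np.mean(x)),
                      sd=sd, min=float(np.min(x)), max=float(np.max(x)))


SEQUENCES = ("yes_yes", "yes_no", "no_yes", "no_no")


def sequence_proportions(responses: Sequence[tuple[str, str]]) -> dict[str, float]:
    """Proportion of each (response1, response2) sequence within a group."""
    if len(responses) == 0:
        raise DataError("cannot compute sequence proportions for an empty group")
    counts = dict.fromkeys(SEQUENCES, 0)
    for r1, r2 in responses:
        key = f"{r1}_{r2}"
        if key not in counts:
            raise DataError(f"illegal response pair ({r1!r}, {r2!r})")
        counts[key] += 1
    n = len(responses)
    return {k: v / n for k, v in counts.items()}


def two_sample_t(values_a: Iterable[float], values_b: Iterable[float]) -> tuple[float, int, float]:
    """Pooled-variance Student t-test with a two-sided p-value.

    Degenerate zero-pooled-variance data: equal means return
    (t=0, df, p=1) by convention; unequal means are an error.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("t-test requires at least 2 observations per group")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / df
    diff = float(np.mean(a) - np.mean(b))
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        raise DataError("zero pooled variance with unequal means: t undefined")
    se = np.sqrt(pooled_var * (1 / a.size + 1 / b.size))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
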