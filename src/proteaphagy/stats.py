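"""Shared statistics: the two-sample t-test used throughout the figures."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class TTestResult:
    t: float
    df: float
    p_value: float


def two_sample_ttest(a, b, variant: str = "student") -> TTestResult:
    """Two-tailed unpaired t-test between two groups.

    ``student`` pools the variance (the default, matching the standard
    figure-legend convention); ``welch`` does not assume equal
    variances.  Identical groups return t = 0, p = 1; a zero pooled
    variance with unequal means is reported as the p -> 0 limit with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    equal_var = variant == "student"
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = len(a) + len(b) - 2.0
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p_value=1.0)
        warnings.warn("zero variance with unequal means: p reported as the 0 limit")
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(t=sign * float("inf"), df=df, p_value=0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2.0
    else:
        df = float(res.df)
    t = float(res.statistic)
    if t == 0.0:
        # exact means equality: avoid p marginally below 1 from roundoff
        return TTestResult(t=0.0, df=df, p_value=1.0)
    return TTestResult(t=t, df=df, p_value=float(res.pvalue))


def significance_stars(p: float) -> str:
    """Figure-legend star convention: 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"
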