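"""Statistical primitives shared across the pipeline.

Thin, defensively wrapped interfaces over :mod:`scipy.stats` with the exact
conventions the rest of the package relies on: the two-sample
Kolmogorov-Smirnov test switches to exact enumeration for small samples,
Spearman's rho uses average ranks with a t-approximation p-value, the one-way
ANOVA is the classical fixed-effects F test, and percentiles follow the
linear-interpolation convention h = (n - 1) * q.

Degenerate inputs (zero variance, constant vectors) are resolved here rather
than propagating NaNs from the underlying library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ks_two_sample",
    "spearman_rho",
    "one_way_anova",
    "t_test_two_tailed",
    "percentile",
    "benjamini_hochberg",
]

#: sample-size product below which the K-S null distribution is exact
KS_EXACT_MAX_NM = 10_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is NaN (and ``defined`` False) when the test is undefined
    for the given input, e.g. Spearman's rho on a constant vector.
    """

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    defined: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|.  The p-value is computed from the exact null
    distribution when ``n * m <= KS_EXACT_MAX_NM`` and from the asymptotic
    Kolmogorov distribution with effective sample size n*m/(n+m) otherwise.
    """
    xa = _as1d(x, "x")
    ya = _as1d(y, "y")
    method = "exact" if xa.size * ya.size <= KS_EXACT_MAX_NM else "asymp"
    res = sps.ks_2samp(xa, ya, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(xa.size, ya.size),
        method=f"ks_two_sample[{method}]",
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (average ranks; t-approximation p, n-2 df).

    A constant input vector leaves the correlation undefined; the result is
    returned flagged (``defined=False``) with NaN statistic rather than
    raising, so callers can report "not computable" per stratum.
    """
    xa = _as1d(x, "x")
    ya = _as1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return TestResult(math.nan, math.nan, (xa.size,), "spearman_rho", defined=False)
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(float(rho), float(min(p, 1.0)), (xa.size,), "spearman_rho")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical fixed-effects one-way ANOVA F test.

    Degenerate layouts are resolved explicitly: zero between- and
    within-group variance gives F=0, p=1; zero within-group variance with
    distinct group means gives F=inf, p=0.
    """
    gs = [_as1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    ns = tuple(g.size for g in gs)
    grand = np.concatenate(gs)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in gs)
    if ssw == 0.0:
        if ssb <= 1e-300:
            return TestResult(0.0, 1.0, ns, "one_way_anova[degenerate]")
        return TestResult(math.inf, 0.0, ns, "one_way_anova[degenerate]")
    f, p = sps.f_oneway(*gs)
    return TestResult(float(f), float(min(p, 1.0)), ns, "one_way_anova")


def t_test_two_tailed(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
) -> TestResult:
    """Two-tailed Student's t-test (equal-variance default; Welch optional)."""
    xa = _as1d(x, "x")
    ya = _as1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("t-test requires n >= 2 per group")
    if paired:
        if xa.size != ya.size:
            raise ValueError("paired t-test requires equal lengths")
        d = xa - ya
        if np.ptp(d) == 0 and abs(d.mean()) <= 1e-300:
            return TestResult(0.0, 1.0, (xa.size,), "t_test[paired,degenerate]")
        t, p = sps.ttest_rel(xa, ya)
        return TestResult(float(t), float(min(p, 1.0)), (xa.size,), "t_test[paired]")
    if np.ptp(xa) == 0 and np.ptp(ya) == 0:
        if abs(xa.mean() - ya.mean()) <= 1e-300:
            return TestResult(0.0, 1.0, (xa.size, ya.size), "t_test[degenerate]")
        sign = math.copysign(1.0, xa.mean() - ya.mean())
        return TestResult(sign * math.inf, 0.0, (xa.size, ya.size), "t_test[degenerate]")
    t, p = sps.ttest_ind(xa, ya, equal_var=equal_var)
    label = "t_test[student]" if equal_var else "t_test[welch]"
    return TestResult(float(t), float(min(p, 1.0)), (xa.size, ya.size), label)


def percentile(values: Sequence[float], q: float) -> float:
    """Percentile under the linear-interpolation convention h = (n - 1) * q.

    ``q`` is a fraction in [0, 1]; q=0.75 on {1,2,3,4} gives 3.25.
    """
    arr = _as1d(values, "values")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(arr, q, method="linear"))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional helper, off by default
    in the differential-expression pipeline)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
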