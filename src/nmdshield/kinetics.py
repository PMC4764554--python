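"""Reporter mRNA decay kinetics and related ratio quantifications.

Decay time courses (band intensities normalized to a co-transfected control
and rescaled to the first time point) are fit by ordinary least squares on
the semilog scale: ln(abundance) = intercept - k_decay * t, with
t_half = ln2 / k_decay.  The 95% confidence interval on the half-life is the
slope's t-based interval with endpoints transformed through t = ln2 / k.
Slope differences between constructs are tested by two-tailed ANCOVA (the F
test on the time x group interaction).  ΔΔCt relative abundance and
immunoprecipitation relative-recovery helpers complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DecayTimeCourse",
    "DecayFit",
    "normalize_timecourse",
    "fit_exponential_decay",
    "compare_slopes_ancova",
    "delta_delta_ct",
    "relative_recovery",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayTimeCourse:
    """One construct/replicate time course: fraction of RNA remaining
    (first time point = 1) at strictly increasing times in minutes."""

    construct: str
    replicate: str
    time: tuple[float, ...]
    abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.time) != len(self.abundance):
            raise ValueError("time and abundance lengths differ")
        if any(t2 <= t1 for t1, t2 in zip(self.time, self.time[1:])):
            raise ValueError("times must be strictly increasing")
        if any(a <= 0 for a in self.abundance):
            raise ValueError("abundances must be positive")


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit.  ``t_half`` is NaN when the estimated rate is
    non-positive (``resolved`` False); the half-life is then only bounded
    below by the last observed time point (``t_half_lower_bound``)."""

    k_decay: float
    t_half: float
    ci95: tuple[float, float]
    r_squared: float
    n_points: int
    resolved: bool
    t_half_lower_bound: float | None = None

    def __str__(self) -> str:
        if not self.resolved:
            return f"t1/2 > {self.t_half_lower_bound:g} min (decay not resolved)"
        lo, hi = self.ci95
        hi_s = f"{hi:.1f}" if math.isfinite(hi) else "inf"
        return f"t1/2 = {self.t_half:.1f} min (95% CI {lo:.1f}-{hi_s})"


def normalize_timecourse(
    raw_exp: Sequence[float],
    raw_ctrl: Sequence[float],
    times: Sequence[float],
    construct: str = "",
    replicate: str = "",
) -> DecayTimeCourse:
    """Experimental/control band ratios rescaled so the first point is 1."""
    exp = np.asarray(raw_exp, dtype=float)
    ctrl = np.asarray(raw_ctrl, dtype=float)
    if exp.shape != ctrl.shape or exp.size != len(times):
        raise ValueError("mismatched lengths")
    if (ctrl <= 0).any():
        raise ValueError("zero/negative control band")
    if (exp <= 0).any():
        raise ValueError("zero/negative experimental band")
    ratio = exp / ctrl
    ratio = ratio / ratio[0]
    return DecayTimeCourse(construct, replicate, tuple(float(t) for t in times),
                           tuple(float(r) for r in ratio))


def fit_exponential_decay(
    timecourses: DecayTimeCourse | Sequence[DecayTimeCourse],
) -> DecayFit:
    """OLS of ln(abundance) on time, pooling replicates into one regression.

    k_decay = -slope; the 95% CI on t_half transforms the endpoints of the
    slope's t-based interval.  A non-positive estimated rate leaves the
    half-life unresolved (bounded below by the last time point).
    """
    if isinstance(timecourses, DecayTimeCourse):
        timecourses = [timecourses]
    t = np.concatenate([tc.time for tc in timecourses])
    y = np.log(np.concatenate([tc.abundance for tc in timecourses]))
    if t.size < 3 or np.unique(t).size < 2:
        raise ValueError("need >= 3 points spanning >= 2 distinct times")
    res = sps.linregress(t, y)
    slope, r = res.slope, res.rvalue
    k = -slope
    df = t.size - 2
    tcrit = sps.t.ppf(0.975, df)
    slope_lo = slope - tcrit * res.stderr
    slope_hi = slope + tcrit * res.stderr
    k_lo, k_hi = -slope_hi, -slope_lo  # k bounds from slope bounds
    last_t = float(t.max())
    if k <= 0:
        return DecayFit(
            k_decay=float(k), t_half=math.nan, ci95=(math.nan, math.nan),
            r_squared=float(r**2), n_points=int(t.size), resolved=False,
            t_half_lower_bound=last_t,
        )
    t_half = LN2 / k
    ci_lo = LN2 / k_hi if k_hi > 0 else math.nan
    ci_hi = LN2 / k_lo if k_lo > 0 else math.inf
    return DecayFit(
        k_decay=float(k), t_half=float(t_half), ci95=(float(ci_lo), float(ci_hi)),
        r_squared=float(r**2), n_points=int(t.size), resolved=True,
    )


def compare_slopes_ancova(
    groups: Mapping[str, Sequence[tuple[float, float]]],
    use_replicate_means: bool = False,
) -> dict:
    """Two-tailed ANCOVA for equality of decay slopes among constructs.

    ``groups`` maps construct name -> (time, ln abundance) points (pooled
    replicates by default).  The model ln(abundance) ~ time * construct is
    fit by OLS and the p-value is the F test on the time x construct
    interaction; with two groups F equals the square of the classical
    two-slope t statistic.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for name, pts in groups.items():
        pts = list(pts)
        if len(pts) < 3:
            raise ValueError(f"group {name!r} needs >= 3 points")
        for t, lna in pts:
            rows.append({"time": float(t), "lna": float(lna), "grp": str(name)})
    df = pd.DataFrame(rows)
    if use_replicate_means:
        df = df.groupby(["grp", "time"], as_index=False)["lna"].mean()
    model = smf.ols("lna ~ time * C(grp)", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("singular ANCOVA design")
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["time:C(grp)"]
    F = float(row["F"])
    p = float(row["PR(>F)"])
    if np.isnan(F):  # perfectly identical groups leave a zero interaction SS
        F, p = 0.0, 1.0
    return {"F": F, "p_value": min(p, 1.0) if not np.isnan(p) else 1.0,
            "df_num": float(row["df"]), "df_den": float(model.df_resid)}


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative abundance 2^(-ΔΔCt) of the target transcript in the treated
    vs control condition, each normalized to the reference transcript."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def relative_recovery(
    bound_exp: float,
    total_exp: float,
    bound_ctrl: float,
    total_ctrl: float,
    reference_value: float = 1.0,
) -> float:
    """Immunoprecipitation recovery of the experimental RNA, normalized to
    the co-expressed control RNA's recovery and then to a designated
    reference condition's value (set the reference condition to 1 by passing
    its own un-referenced recovery)."""
    if total_exp <= 0 or total_ctrl <= 0 or bound_ctrl <= 0 or reference_value <= 0:
        raise ValueError("totals, control recovery and reference must be positive")
    return (bound_exp / total_exp) / (bound_ctrl / total_ctrl) / reference_value
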