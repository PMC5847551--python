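"""Used vs not-used comparison: one-way two-group linear model on
arcsine-square-root-transformed lit-pixel proportions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InputError

_TOL = 1e-9


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_two_sided: float
    mean_diff: float  # transformed scale, group1 - group2
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    mean1_transformed: float
    mean2_transformed: float
    mean1_raw: float
    mean2_raw: float


def arcsine_sqrt(p):
    """asin(sqrt(p)) in radians; proportions outside [0,1] by <= 1e-9 are clamped."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -_TOL) or np.any(arr > 1 + _TOL):
        raise DomainError("proportion outside [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out


def compare_use(
    values_used,
    values_not_used,
    transform: bool = True,
    conf: float = 0.95,
) -> AnovaResult:
    """Two-group one-way ANOVA on (optionally transformed) lit proportions.

    F equals the square of the pooled two-sample t statistic; the CI of the
    group-mean difference is the pooled-variance t interval on the analysis
    scale. Raw-scale group means are reported alongside.
    """
    raw1 = np.asarray(values_used, dtype=float)
    raw2 = np.asarray(values_not_used, dtype=float)
    if raw1.size < 2 or raw2.size < 2:
        raise InputError("both groups need >= 2 members")
    g1 = arcsine_sqrt(raw1) if transform else raw1
    g2 = arcsine_sqrt(raw2) if transform else raw2
    n1, n2 = g1.size, g2.size
    m1, m2 = float(g1.mean()), float(g2.mean())
    df_w = n1 + n2 - 2
    ss_w = float(((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum())
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ss_b = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    # degenerate data: zero out rounding dust relative to the data scale
    scale = float((g1**2).sum() + (g2**2).sum())
    eps = 1e-24 * max(scale, 1.0)
    ss_w = 0.0 if ss_w <= eps else ss_w
    ss_b = 0.0 if ss_b <= eps else ss_b
    if ss_w <= 0:
        if ss_b <= 0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
        se = 0.0
    else:
        ms_w = ss_w / df_w
        F = float(ss_b / ms_w)
        p = float(stats.f.sf(F, 1, df_w))
        se = float(np.sqrt(ms_w * (1 / n1 + 1 / n2)))
    diff = m1 - m2
    tcrit = float(stats.t.ppf(0.5 + conf / 2.0, df=df_w)) if df_w > 0 else float("nan")
    return AnovaResult(
        F=F,
        df_between=1,
        df_within=df_w,
        p_two_sided=p,
        mean_diff=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        n1=n1,
        n2=n2,
        mean1_transformed=m1,
        mean2_transformed=m2,
        mean1_raw=float(raw1.mean()),
        mean2_raw=float(raw2.mean()),
    )
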