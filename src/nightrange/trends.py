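"""Mann-Kendall monotonic trend test, from first principles.

S is the signed concordance sum over ordered pairs; its variance carries the
standard tie correction; tau is the tie-adjusted tau-b; the normal deviate
uses the classic continuity correction. An exact small-n p-value (full null
distribution of S) is available for tie-free series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class TrendResult:
    series_id: str
    n: int
    S: int
    var_S: float
    tau: float
    z: float
    p_two_sided: float


def _s_statistic(x: np.ndarray) -> int:
    d = np.sign(x[None, :] - x[:, None])
    return int(np.triu(d, k=1).sum())


def _tie_groups(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1]


def _exact_p(n: int, S: int) -> float:
    """Two-sided exact p for tie-free series via the null distribution of S.

    The count of permutations with k inversions follows the generating
    function prod_{j=1..n} (1 + q + ... + q^{j-1}); S = n(n-1)/2 - 2k.
    """
    counts = np.array([1.0])
    for j in range(2, n + 1):
        counts = np.convolve(counts, np.ones(j))
    total = counts.sum()
    n0 = n * (n - 1) // 2
    # S values run n0, n0-2, ..., -n0 as inversions run 0..n0
    s_vals = n0 - 2 * np.arange(counts.size)
    p_ge = counts[s_vals >= abs(S)].sum() / total
    return float(min(1.0, 2.0 * p_ge)) if S != 0 else 1.0


def mann_kendall(
    series: Sequence[float], series_id: str = "", exact: bool = False
) -> TrendResult:
    """Mann-Kendall test on a time-ordered series (n >= 3).

    With ``exact`` and n <= 10 and no ties, the p-value comes from the exact
    null distribution of S; otherwise the continuity-corrected normal
    approximation is used. A fully tied series returns tau = 0, p = 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InputError(f"series must be 1-D with n >= 3, got n={x.size}")
    n = x.size
    S = _s_statistic(x)
    ties = _tie_groups(x)
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    n0 = n * (n - 1) / 2.0
    n_ties = float(np.sum(ties * (ties - 1) / 2.0))
    denom = np.sqrt((n0 - n_ties) * n0)  # time axis has no ties
    tau = S / denom if denom > 0 else 0.0
    if var_S <= 0:  # every value tied
        return TrendResult(series_id, n, S, 0.0, 0.0, 0.0, 1.0)
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    if exact and n <= 10 and ties.size == 0:
        p = _exact_p(n, S)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(series_id, n, S, float(var_S), float(tau), float(z), min(1.0, p))


def mean_lit_series(
    per_species_series: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> np.ndarray:
    """Per-year arithmetic mean of lit-pixel counts across species."""
    if isinstance(per_species_series, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in per_species_series.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in per_species_series]
    if not arrays:
        raise InputError("no series given")
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise InputError(f"series lengths differ: {sorted(lengths)}")
    return np.mean(np.vstack(arrays), axis=0)


def classify_trends(
    results: Iterable[TrendResult], alpha: float = 0.05
) -> dict[str, int]:
    """Counts of significantly positive / negative / no-trend series."""
    results = list(results)
    if not results:
        raise InputError("no trend results given")
    counts = {"positive": 0, "negative": 0, "none": 0}
    for r in results:
        if r.p_two_sided < alpha and r.tau > 0:
            counts["positive"] += 1
        elif r.p_two_sided < alpha and r.tau < 0:
            counts["negative"] += 1
        else:
            counts["none"] += 1
    return counts


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (optional output; no correction
    is applied by default anywhere in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def trend_table(results: Iterable[TrendResult], adjust: bool = False) -> pd.DataFrame:
    """Tidy table of TrendResult fields, optionally with BH q-values."""
    rows = [
        {
            "series_id": r.series_id,
            "n": r.n,
            "S": r.S,
            "var_S": r.var_S,
            "tau": r.tau,
            "z": r.z,
            "p_two_sided": r.p_two_sided,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows, columns=["series_id", "n", "S", "var_S", "tau", "z", "p_two_sided"]
    )
    if adjust and len(df):
        df["q_bh"] = bh_adjust(df["p_two_sided"].to_numpy())
    return df
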