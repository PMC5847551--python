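"""Species-richness grids and the richness-brightness correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridMismatchError, InputError
from .grids import CompositeGrid, GridSpec, RangeMask


@dataclass
class RichnessGrid:
    counts: np.ndarray  # rows x cols non-negative ints
    subset: str  # "all" | "threatened"
    grid: GridSpec

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != self.grid.shape:
            raise GridMismatchError("counts shape does not match grid")

    @property
    def max_richness(self) -> int:
        return int(self.counts.max())


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p_two_sided: float
    defined: bool = True


def build_richness(
    masks: Sequence[RangeMask],
    grid: GridSpec,
    subset: str = "all",
    predicate: Callable[[RangeMask], bool] | None = None,
) -> RichnessGrid:
    """Per-pixel count of overlapping species ranges.

    Conservation holds exactly: the grid total equals the summed pixel counts
    of the included masks.
    """
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        if predicate is not None and not predicate(m):
            continue
        if not m.in_grid(grid):
            raise GridMismatchError(f"mask {m.species_id!r} has off-grid pixels")
        np.add.at(counts, (m.rows, m.cols), 1)
    return RichnessGrid(counts=counts, subset=subset, grid=grid)


def richness_levels(rgrid: RichnessGrid, dn: CompositeGrid) -> pd.DataFrame:
    """One row per occupied richness level: (level, n_pixels, mean_dn)."""
    if dn.grid != rgrid.grid:
        raise GridMismatchError("richness and DN grids differ")
    rows = []
    occupied = np.unique(rgrid.counts)
    for k in occupied[occupied >= 1]:
        sel = rgrid.counts == k
        rows.append(
            {
                "level": int(k),
                "n_pixels": int(sel.sum()),
                "mean_dn": float(np.nanmean(dn.dn[sel])),
            }
        )
    return pd.DataFrame(rows, columns=["level", "n_pixels", "mean_dn"])


def bin_richness(
    rgrid: RichnessGrid, n_classes: int = 5
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Equal-width integer classes over [1, max]; zero-richness pixels stay 0.

    Class width is ceil(max / n_classes), so a maximum of 82 with 5 classes
    gives a first interval of 1-17.
    """
    mx = rgrid.max_richness
    if mx == 0:
        raise InputError("richness grid is all zero; nothing to bin")
    if mx < n_classes:
        raise InputError(f"max richness {mx} < n_classes {n_classes}")
    width = math.ceil(mx / n_classes)
    intervals = []
    lo = 1
    for _ in range(n_classes):
        hi = min(lo + width - 1, mx)
        intervals.append((lo, hi))
        lo = hi + 1
        if lo > mx:
            break
    class_map = np.zeros(rgrid.counts.shape, dtype=np.int64)
    for i, (a, b) in enumerate(intervals, start=1):
        class_map[(rgrid.counts >= a) & (rgrid.counts <= b)] = i
    return class_map, intervals


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> CorrelationResult:
    """Pearson r with Fisher-z CI and t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must align")
    n = x.size
    if n < 4:
        raise InputError(f"need n >= 4 points, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            float("nan"), n, float("nan"), float("nan"), float("nan"), defined=False
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    if abs(r) < 1.0:
        z = math.atanh(r)
        half = zcrit / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        ci_low = ci_high = r
        p = 0.0
    return CorrelationResult(r, n, ci_low, ci_high, p, defined=True)


def richness_brightness_correlation(
    rgrid: RichnessGrid, dn: CompositeGrid, per_pixel: bool = False
) -> CorrelationResult:
    """Correlate richness with brightness.

    Default unit: one point per occupied richness level (level vs the level's
    mean DN). With ``per_pixel``, one point per range pixel (richness count vs
    DN across all pixels with richness >= 1).
    """
    if per_pixel:
        sel = rgrid.counts >= 1
        return pearson_with_ci(rgrid.counts[sel], dn.dn[sel])
    table = richness_levels(rgrid, dn)
    return pearson_with_ci(table["level"], table["mean_dn"])
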