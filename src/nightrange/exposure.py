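"""Per-species exposure to artificial light: lit fractions, mean DN, evenness.

A pixel is "lit" when its DN is at or above the darkness threshold
(default 5.5: dark means strictly less). Period-level statistics are computed
on the period-mean image — the threshold is applied after averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InputError
from .grids import CompositeGrid, RangeMask

#: darkness threshold: DN < 5.5 is dark, DN >= 5.5 is lit
DEFAULT_THRESHOLD = 5.5


@dataclass(frozen=True)
class ExposureRecord:
    species_id: str
    scope: str  # a year "1997" or a period label "1992-1996" / "all-years"
    n_pixels: int
    n_lit: int
    prop_lit: float
    mean_dn: float
    sum_dn: float

    @property
    def pct_range_lit(self) -> float:
        return 100.0 * self.prop_lit


@dataclass(frozen=True)
class EvennessResult:
    species_id: str
    period: str
    frac_pixels_for_95: float
    defined: bool


def classify_lit(dn, threshold: float = DEFAULT_THRESHOLD):
    """True where DN is lit (dn >= threshold). Works on scalars and arrays."""
    return np.greater_equal(dn, threshold)


def period_mean(stack: Sequence[CompositeGrid], years: Sequence[int]) -> CompositeGrid:
    """Per-pixel arithmetic mean DN over the requested years.

    Nodata propagates: a pixel that is nodata in any member is nodata in the
    mean (members use NaN internally for nodata).
    """
    by_year = {g.year: g for g in stack}
    missing = [y for y in years if y not in by_year]
    if missing:
        raise InputError(f"years missing from stack: {missing}")
    if not years:
        raise InputError("no years requested")
    members = [by_year[y] for y in years]
    ref = members[0].grid
    for g in members[1:]:
        if g.grid != ref:
            raise GridMismatchError("period members on different grids")
    acc = np.zeros(ref.shape, dtype=float)
    any_nodata = np.zeros(ref.shape, dtype=bool)
    for g in members:
        valid = g.valid_mask
        any_nodata |= ~valid
        acc += np.where(valid, g.dn, 0.0)
    mean = acc / len(members)
    mean[any_nodata] = np.nan
    label = f"mean {years[0]}-{years[-1]}" if len(years) > 1 else f"mean {years[0]}"
    return CompositeGrid(
        year=int(years[len(years) // 2]),
        dn=mean,
        grid=ref,
        satellite_label=label,
    )


def range_exposure(
    grid: CompositeGrid,
    mask: RangeMask,
    threshold: float = DEFAULT_THRESHOLD,
    scope: str | None = None,
) -> ExposureRecord:
    """Lit count/fraction and DN summaries of one species on one image."""
    vals = mask.values(grid)  # raises GridMismatchError if outside
    n_lit = int(np.count_nonzero(classify_lit(vals, threshold)))
    return ExposureRecord(
        species_id=mask.species_id,
        scope=scope if scope is not None else str(grid.year),
        n_pixels=mask.n_pixels,
        n_lit=n_lit,
        prop_lit=n_lit / mask.n_pixels,
        mean_dn=float(np.nanmean(vals)),
        sum_dn=float(np.nansum(vals)),
    )


def annual_lit_series(
    stack: Sequence[CompositeGrid],
    mask: RangeMask,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[int, int]]:
    """Year-ordered (year, lit-pixel count) pairs for one species."""
    out = []
    for g in sorted(stack, key=lambda g: g.year):
        vals = mask.values(g)
        out.append((g.year, int(np.count_nonzero(classify_lit(vals, threshold)))))
    return out


def evenness_95(
    grid: CompositeGrid, mask: RangeMask, q: float = 0.95, period: str | None = None
) -> EvennessResult:
    """Smallest fraction of range pixels accounting for q of the range's ΣDN.

    Pixels are sorted by DN descending; the result is k/n for the smallest k
    whose cumulative DN reaches q*ΣDN. Undefined (flagged) when ΣDN = 0.
    """
    vals = mask.values(grid)
    vals = np.where(np.isnan(vals), 0.0, vals)
    total = float(vals.sum())
    label = period if period is not None else str(grid.year)
    if total <= 0:
        return EvennessResult(mask.species_id, label, float("nan"), defined=False)
    s = np.sort(vals)[::-1]
    csum = np.cumsum(s)
    k = int(np.searchsorted(csum, q * total)) + 1
    return EvennessResult(mask.species_id, label, k / mask.n_pixels, defined=True)


def all_years_mean_dn(
    stack: Sequence[CompositeGrid], mask: RangeMask
) -> float:
    """Mean over years of the per-year range-mean DN."""
    if not stack:
        raise InputError("empty stack")
    return float(np.mean([np.nanmean(mask.values(g)) for g in stack]))


def exposure_table(
    stack: Sequence[CompositeGrid],
    masks: Sequence[RangeMask],
    threshold: float = DEFAULT_THRESHOLD,
    periods: dict[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Tidy per-species exposure: one row per species x scope.

    Scopes are every year in the stack, every named period (computed on the
    period-mean image), and "all-years" (mean over years of per-year values).
    """
    rows: list[dict] = []

    def rec_to_row(rec: ExposureRecord) -> dict:
        return {
            "species_id": rec.species_id,
            "scope": rec.scope,
            "n_pixels": rec.n_pixels,
            "n_lit": rec.n_lit,
            "prop_lit": rec.prop_lit,
            "pct_range_lit": rec.pct_range_lit,
            "mean_dn": rec.mean_dn,
            "sum_dn": rec.sum_dn,
        }

    period_grids = {}
    if periods:
        for label, yrs in periods.items():
            period_grids[label] = period_mean(stack, yrs)
    for m in masks:
        per_year = []
        for g in stack:
            rec = range_exposure(g, m, threshold)
            per_year.append(rec)
            rows.append(rec_to_row(rec))
        rows.append(
            {
                "species_id": m.species_id,
                "scope": "all-years",
                "n_pixels": m.n_pixels,
                "n_lit": float(np.mean([r.n_lit for r in per_year])),
                "prop_lit": float(np.mean([r.prop_lit for r in per_year])),
                "pct_range_lit": float(np.mean([r.pct_range_lit for r in per_year])),
                "mean_dn": float(np.mean([r.mean_dn for r in per_year])),
                "sum_dn": float(np.mean([r.sum_dn for r in per_year])),
            }
        )
        for label, pg in period_grids.items():
            rows.append(rec_to_row(range_exposure(pg, m, threshold, scope=label)))
    cols = [
        "species_id",
        "scope",
        "n_pixels",
        "n_lit",
        "prop_lit",
        "pct_range_lit",
        "mean_dn",
        "sum_dn",
    ]
    return pd.DataFrame(rows, columns=cols)


def evenness_table(
    stack: Sequence[CompositeGrid],
    masks: Sequence[RangeMask],
    periods: dict[str, Sequence[int]],
    q: float = 0.95,
) -> pd.DataFrame:
    """Per-species evenness statistic on each period-mean image."""
    rows = []
    for label, yrs in periods.items():
        pg = period_mean(stack, yrs)
        for m in masks:
            res = evenness_95(pg, m, q=q, period=label)
            rows.append(
                {
                    "species_id": res.species_id,
                    "period": res.period,
                    "frac_pixels_for_95": res.frac_pixels_for_95,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(rows, columns=["species_id", "period", "frac_pixels_for_95", "defined"])
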