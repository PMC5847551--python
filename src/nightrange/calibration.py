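"""Intercalibration of a multi-year composite stack.

Every non-reference year is mapped onto the reference year's DN scale by a
second-order polynomial fitted by quantile regression through the median
(an L1 fit, insensitive to pixels that genuinely changed). The L1 problem is
solved exactly as a linear program; determinism comes from the solver.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import GridMismatchError, InputError, InsufficientDataError, RankError
from .grids import DN_MAX, CompositeGrid

MIN_PIXELS = 30
IDENTITY = (0.0, 1.0, 0.0)


@dataclass(frozen=True)
class StablePixelOptions:
    """How stable pixels are chosen before the median fit."""

    trim: bool = False
    k: float = 3.0  # MAD multiplier for trimming
    max_iter: int = 5
    max_pixels: int | None = 8_000  # deterministic subsample cap; None = all
    subsample_seed: int = 0
    #: fall back to identity coefficients (with a warning) for years with too
    #: few co-lit pixels instead of raising — used by the pipeline so that
    #: fully dark stacks still flow through.
    fallback_identity: bool = False


@dataclass
class CalibrationModel:
    """Per-year quadratic coefficients mapping each year onto the reference scale."""

    reference_year: int
    coefficients: dict[int, tuple[float, float, float]]
    diagnostics: dict[int, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "reference_year": self.reference_year,
            "coefficients": {str(y): list(c) for y, c in self.coefficients.items()},
            "diagnostics": {str(y): d for y, d in self.diagnostics.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CalibrationModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            reference_year=int(doc["reference_year"]),
            coefficients={int(y): tuple(c) for y, c in doc["coefficients"].items()},
            diagnostics={int(y): d for y, d in doc.get("diagnostics", {}).items()},
        )


def fit_calibration(
    reference_dn: Sequence[float], target_dn: Sequence[float]
) -> tuple[float, float, float]:
    """Median (L1) quadratic fit: reference ≈ c0 + c1*target + c2*target².

    Solved exactly as the LP  min Σ(u+v)  s.t.  Xc + u − v = ref, u,v ≥ 0.
    Deterministic for fixed input.
    """
    ref = np.asarray(reference_dn, dtype=float)
    tgt = np.asarray(target_dn, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 1:
        raise InputError("reference and target must be aligned 1-D value lists")
    n = ref.size
    if n < MIN_PIXELS:
        raise InsufficientDataError(f"need >= {MIN_PIXELS} paired pixels, got {n}")
    if np.unique(tgt).size < 3:
        raise RankError("target DN spans too few distinct values for a quadratic fit")
    # scale the regressor to [0, 1] for LP conditioning; unscale coefficients after
    s = float(tgt.max())
    s = s if s > 0 else 1.0
    t = tgt / s
    X = sparse.csc_matrix(np.column_stack([np.ones(n), t, t * t]))
    eye = sparse.eye(n, format="csc")
    A_eq = sparse.hstack([X, eye, -eye], format="csc")
    c_obj = np.concatenate([np.zeros(3), np.ones(2 * n)])
    bounds = [(None, None)] * 3 + [(0, None)] * (2 * n)
    res = linprog(c_obj, A_eq=A_eq, b_eq=ref, bounds=bounds, method="highs")
    if not res.success:
        raise InsufficientDataError(f"L1 solver failed: {res.message}")
    b0, b1, b2 = res.x[:3]
    return (float(b0), float(b1 / s), float(b2 / s / s))


def _l1_residuals(ref: np.ndarray, tgt: np.ndarray, coeffs) -> np.ndarray:
    c0, c1, c2 = coeffs
    return ref - (c0 + c1 * tgt + c2 * tgt * tgt)


def select_stable_pixels(
    reference: CompositeGrid,
    target: CompositeGrid,
    opts: StablePixelOptions = StablePixelOptions(),
) -> np.ndarray:
    """Pixels used for calibration, as an (n, 2) array of (row, col).

    Default: every pixel lit in both images (reference DN > 0 and target
    DN > 0) — the median fit absorbs genuinely changed pixels. With
    ``opts.trim`` the set is iteratively pruned of pixels whose absolute fit
    residual exceeds k*MAD (scaled), refitting up to ``max_iter`` times.
    """
    if reference.grid != target.grid:
        raise GridMismatchError("reference and target grids differ")
    co_lit = (
        (reference.dn > 0)
        & (target.dn > 0)
        & reference.valid_mask
        & target.valid_mask
    )
    rows, cols = np.nonzero(co_lit)
    if rows.size < MIN_PIXELS:
        raise InsufficientDataError(
            f"only {rows.size} co-lit pixels; need >= {MIN_PIXELS}"
        )
    if opts.max_pixels is not None and rows.size > opts.max_pixels:
        rng = np.random.default_rng(opts.subsample_seed)
        pick = rng.choice(rows.size, size=opts.max_pixels, replace=False)
        pick.sort()
        rows, cols = rows[pick], cols[pick]
    if opts.trim:
        keep = np.ones(rows.size, dtype=bool)
        for _ in range(opts.max_iter):
            ref_v = reference.dn[rows[keep], cols[keep]]
            tgt_v = target.dn[rows[keep], cols[keep]]
            coeffs = fit_calibration(ref_v, tgt_v)
            resid = np.abs(
                _l1_residuals(
                    reference.dn[rows, cols], target.dn[rows, cols], coeffs
                )
            )
            mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
            scale = 1.4826 * mad
            if scale <= 0:
                break
            new_keep = resid <= opts.k * scale
            if new_keep.sum() < MIN_PIXELS or bool((new_keep == keep).all()):
                keep = new_keep if new_keep.sum() >= MIN_PIXELS else keep
                break
            keep = new_keep
        rows, cols = rows[keep], cols[keep]
    return np.column_stack([rows, cols])


def apply_calibration(
    grid: CompositeGrid, coeffs: tuple[float, float, float]
) -> CompositeGrid:
    """Map a composite onto the reference scale: clamp(c0 + c1*dn + c2*dn², 0, 63).

    DN = 0 maps to 0 regardless of c0 (a dark pixel stays dark); output kept
    fractional; nodata untouched.
    """
    c0, c1, c2 = coeffs
    if not all(np.isfinite([c0, c1, c2])):
        raise InputError("calibration coefficients must be finite")
    dn = grid.dn
    out = np.clip(c0 + c1 * dn + c2 * dn * dn, 0.0, DN_MAX)
    out = np.where(dn == 0, 0.0, out)
    out = np.where(grid.valid_mask, out, grid.dn)
    return grid.copy_with(dn=out)


def _warn_if_nonmonotone(coeffs, year: int) -> None:
    c0, c1, c2 = coeffs
    # derivative c1 + 2*c2*x on [0, 63] is linear; check both ends
    if min(c1, c1 + 2 * c2 * DN_MAX) < 0:
        warnings.warn(
            f"calibration map for year {year} is non-monotone on [0, 63] "
            f"(coeffs {coeffs})",
            stacklevel=3,
        )


def calibrate_stack(
    stack: Sequence[CompositeGrid],
    reference_year: int | None = None,
    opts: StablePixelOptions = StablePixelOptions(),
) -> tuple[list[CompositeGrid], CalibrationModel]:
    """Calibrate every year of a stack onto the reference year's scale.

    The reference defaults to the stack's middle year. The reference grid is
    returned unchanged with identity coefficients.
    """
    stack = sorted(stack, key=lambda g: g.year)
    if not stack:
        raise InputError("empty stack")
    years = [g.year for g in stack]
    if reference_year is None:
        reference_year = years[len(years) // 2]
    if reference_year not in years:
        raise InputError(f"reference year {reference_year} not in stack {years}")
    reference = next(g for g in stack if g.year == reference_year)
    calibrated: list[CompositeGrid] = []
    coefficients: dict[int, tuple[float, float, float]] = {}
    diagnostics: dict[int, dict] = {}
    for g in stack:
        if g.year == reference_year:
            coefficients[g.year] = IDENTITY
            diagnostics[g.year] = {"n_stable": None, "median_abs_residual": 0.0}
            calibrated.append(g.copy_with(dn=g.dn.copy()))
            continue
        try:
            idx = select_stable_pixels(reference, g, opts)
            ref_v = reference.dn[idx[:, 0], idx[:, 1]]
            tgt_v = g.dn[idx[:, 0], idx[:, 1]]
            coeffs = fit_calibration(ref_v, tgt_v)
        except (InsufficientDataError, RankError) as exc:
            if not opts.fallback_identity:
                raise
            warnings.warn(
                f"year {g.year}: {exc}; keeping identity calibration", stacklevel=2
            )
            coefficients[g.year] = IDENTITY
            diagnostics[g.year] = {"n_stable": 0, "median_abs_residual": None,
                                   "fallback": str(exc)}
            calibrated.append(g.copy_with(dn=g.dn.copy()))
            continue
        _warn_if_nonmonotone(coeffs, g.year)
        coefficients[g.year] = coeffs
        diagnostics[g.year] = {
            "n_stable": int(idx.shape[0]),
            "median_abs_residual": float(
                np.median(np.abs(_l1_residuals(ref_v, tgt_v, coeffs)))
            ),
        }
        calibrated.append(apply_calibration(g, coeffs))
    model = CalibrationModel(
        reference_year=reference_year,
        coefficients=coefficients,
        diagnostics=diagnostics,
    )
    return calibrated, model
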