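"""Synthetic nightscapes, sensor distortions and species ranges.

The generator produces a time-ordered stack of DN grids (bounded 0-63, urban
cores saturated at 63), per-year quadratic sensor distortions, and elliptical
species ranges spanning orders of magnitude in pixel count — everything the
downstream stages need, with exact ground truth.

Light is modelled as radial decay around urban seed points whose effective
reach grows geometrically each year; with zero noise every pixel's DN is
non-decreasing in time, so lit area and total brightness grow monotonically
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point

from .errors import ParameterError
from .exposure import DEFAULT_THRESHOLD
from .grids import CompositeGrid, GridSpec, RangeMask, SpeciesRange, rasterize_range

_IDENTITY = (0.0, 1.0, 0.0)


@dataclass(frozen=True)
class NightscapeParams:
    """Parameters of the synthetic true-light stack."""

    grid_rows: int = 200
    grid_cols: int = 400
    n_years: int = 21
    n_urban_seeds: int = 40
    growth_rate: float = 0.05
    base_brightness_decay: float = 8.0  # DN lost per pixel of distance in year 0
    noise_sd: float = 0.0
    seed: int = 0
    start_year: int = 1992
    #: urban seeds are placed with column fraction in this half-open interval,
    #: allowing light to be concentrated away from species-rich areas.
    seed_col_frac: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.grid_rows < 16 or self.grid_cols < 16:
            raise ParameterError("grid dims must be >= 16")
        if self.n_years < 3:
            raise ParameterError("n_years must be >= 3")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.growth_rate < 0:
            raise ParameterError("growth_rate must be >= 0")
        if self.n_urban_seeds < 0:
            raise ParameterError("n_urban_seeds must be >= 0")
        if self.base_brightness_decay <= 0:
            raise ParameterError("base_brightness_decay must be > 0")
        lo, hi = self.seed_col_frac
        if not (0.0 <= lo < hi <= 1.0):
            raise ParameterError("seed_col_frac must satisfy 0 <= lo < hi <= 1")

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.n_years)]


@dataclass(frozen=True)
class DistortionSpec:
    """Per-year quadratic sensor distortions observed = c0 + c1*DN + c2*DN^2 + noise."""

    coeffs: dict[int, tuple[float, float, float]]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not any(np.allclose(c, _IDENTITY) for c in self.coeffs.values()):
            raise ParameterError("an identity year (c0=0, c1=1, c2=0) must exist")

    @classmethod
    def identity(cls, years: Sequence[int]) -> "DistortionSpec":
        return cls(coeffs={y: _IDENTITY for y in years}, noise_sd=0.0)

    @classmethod
    def random(
        cls,
        years: Sequence[int],
        seed: int = 0,
        noise_sd: float = 0.5,
        identity_year: int | None = None,
    ) -> "DistortionSpec":
        """Mild monotone quadratics per year; one year kept at identity."""
        rng = np.random.default_rng(seed)
        if identity_year is None:
            identity_year = years[len(years) // 2]
        coeffs = {}
        for y in years:
            if y == identity_year:
                coeffs[y] = _IDENTITY
                continue
            c0 = float(rng.uniform(-2.0, 2.0))
            c1 = float(rng.uniform(0.85, 1.25))
            c2 = float(rng.uniform(-0.003, 0.001))
            # keep the map increasing on [0, 63]
            if c1 + 2 * c2 * 63 <= 0.05:
                c2 = (0.05 - c1) / (2 * 63)
            coeffs[y] = (c0, c1, c2)
        return cls(coeffs=coeffs, noise_sd=noise_sd)


@dataclass(frozen=True)
class RangeParams:
    """Parameters of the synthetic species-range collection."""

    n_species: int = 1435
    range_size_min: int = 1
    range_size_max: int = 10_000
    frac_used: float = 838 / 1435
    frac_threatened: float = 417 / 1435
    seed: int = 0
    #: density of range centers along the column axis is proportional to
    #: (col fraction)^col_weight_power — 0 means uniform; > 0 concentrates
    #: species richness toward high columns.
    col_weight_power: float = 0.0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ParameterError("n_species must be >= 0")
        if self.range_size_min < 1:
            raise ParameterError("range_size_min must be >= 1")
        if self.range_size_max < self.range_size_min:
            raise ParameterError("range_size_max must be >= range_size_min")
        for name in ("frac_used", "frac_threatened"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.col_weight_power < 0:
            raise ParameterError("col_weight_power must be >= 0")


def default_grid_spec(rows: int, cols: int, pixel_size: float = 1000.0) -> GridSpec:
    """Equal-area grid with the origin at (0, rows*pixel) so y decreases with row."""
    return GridSpec(
        rows=rows,
        cols=cols,
        pixel_width=pixel_size,
        pixel_height=pixel_size,
        origin_x=0.0,
        origin_y=rows * pixel_size,
    )


def make_nightscape(
    params: NightscapeParams, grid_spec: GridSpec | None = None
) -> list[CompositeGrid]:
    """Generate the true (undistorted) DN stack, one grid per year.

    DN at pixel p in year t is ``clip(63 - decay_t * dist(p, nearest seed))``
    with ``decay_t = base_brightness_decay / (1 + growth_rate)^t``: cores stay
    saturated at 63 while the lit fringe creeps outward each year. Gaussian
    noise (sd ``noise_sd``) is added only where the noiseless field is
    positive, so truly dark pixels never emit.
    """
    if grid_spec is None:
        grid_spec = default_grid_spec(params.grid_rows, params.grid_cols)
    if (grid_spec.rows, grid_spec.cols) != (params.grid_rows, params.grid_cols):
        raise ParameterError("grid_spec dims disagree with params")
    rng = np.random.default_rng(params.seed)
    rows, cols = params.grid_rows, params.grid_cols
    if params.n_urban_seeds == 0:
        min_dist = np.full((rows, cols), np.inf)
    else:
        lo, hi = params.seed_col_frac
        c_lo, c_hi = int(lo * cols), max(int(lo * cols) + 1, int(hi * cols))
        # seeds sit on pixel centers so every urban core pixel saturates at 63
        seed_r = rng.integers(0, rows, size=params.n_urban_seeds) + 0.5
        seed_c = rng.integers(c_lo, c_hi, size=params.n_urban_seeds) + 0.5
        rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
        min_dist = np.full((rows, cols), np.inf)
        for sr, sc in zip(seed_r, seed_c):
            d = np.hypot(rr - sr, cc - sc)
            np.minimum(min_dist, d, out=min_dist)
    stack = []
    for t, year in enumerate(params.years):
        decay = params.base_brightness_decay / (1.0 + params.growth_rate) ** t
        with np.errstate(invalid="ignore"):
            base = np.clip(63.0 - decay * min_dist, 0.0, 63.0)
        base = np.nan_to_num(base, nan=0.0)
        dn = base
        if params.noise_sd > 0:
            year_rng = np.random.default_rng([params.seed, year])
            noise = year_rng.normal(0.0, params.noise_sd, size=base.shape)
            dn = np.where(base > 0, np.clip(base + noise, 0.0, 63.0), 0.0)
        stack.append(
            CompositeGrid(year=year, dn=dn, grid=grid_spec, satellite_label="TRUTH")
        )
    return stack


def apply_distortion(
    truth: CompositeGrid, spec: DistortionSpec, seed: int = 0
) -> CompositeGrid:
    """Distort a true composite into an 'observed' one for its year.

    observed = clip(c0 + c1*DN + c2*DN^2 + noise, 0, 63); pixels with true
    DN = 0 stay exactly 0 (stable-light semantics: no false lights).
    """
    if truth.year not in spec.coeffs:
        raise ParameterError(f"no distortion coefficients for year {truth.year}")
    c0, c1, c2 = spec.coeffs[truth.year]
    dn = truth.dn
    obs = c0 + c1 * dn + c2 * dn * dn
    if spec.noise_sd > 0:
        rng = np.random.default_rng([seed, truth.year])
        obs = obs + rng.normal(0.0, spec.noise_sd, size=dn.shape)
    obs = np.clip(obs, 0.0, 63.0)
    obs = np.where(dn == 0, 0.0, obs)
    return truth.copy_with(dn=obs, satellite_label=f"OBS{truth.year}")


def make_ranges(
    params: RangeParams, grid_spec: GridSpec
) -> tuple[list[SpeciesRange], list[RangeMask]]:
    """Generate elliptical species ranges with ground-truth pixel masks.

    Target pixel counts are drawn log-uniformly in
    [range_size_min, range_size_max]; each ellipse's area matches its target
    count times the pixel area. Used/threatened flags are Bernoulli at the
    configured fractions.
    """
    area_needed = params.range_size_max
    if area_needed > grid_spec.n_pixels:
        raise ParameterError(
            f"range_size_max={params.range_size_max} exceeds grid area {grid_spec.n_pixels}"
        )
    rng = np.random.default_rng(params.seed)
    xmin, ymin, xmax, ymax = grid_spec.bounds
    width, height = xmax - xmin, ymax - ymin
    ranges: list[SpeciesRange] = []
    masks: list[RangeMask] = []
    for i in range(params.n_species):
        size = math.exp(
            rng.uniform(math.log(params.range_size_min), math.log(params.range_size_max + 1))
        )
        target_area = size * grid_spec.pixel_area
        aspect = rng.uniform(0.5, 2.0)
        # pi * a * b = target_area with a = aspect * b
        b = math.sqrt(target_area / (math.pi * aspect))
        a = aspect * b
        u = rng.uniform()
        if params.col_weight_power > 0:
            u = u ** (1.0 / (params.col_weight_power + 1.0))
        cx = xmin + u * width
        cy = ymin + rng.uniform() * height
        angle = rng.uniform(0, 180)
        circ = Point(cx, cy).buffer(1.0, quad_segs=24)
        geom = affinity.rotate(affinity.scale(circ, a, b), angle)
        threatened = rng.uniform() < params.frac_threatened
        used = rng.uniform() < params.frac_used
        category = str(rng.choice(["CR", "EN", "VU"] if threatened else ["LC", "NT"]))
        n_use = int(rng.integers(1, 4)) if used else 0
        from .grids import USE_CATEGORIES

        use_cats = tuple(rng.choice(USE_CATEGORIES, size=n_use, replace=False)) if n_use else ()
        sr = SpeciesRange(
            species_id=f"SP{i:04d}",
            name=f"Synthetic species {i}",
            geometry=geom,
            category=category,
            used=used,
            use_categories=use_cats,
        )
        ranges.append(sr)
        masks.append(rasterize_range(sr, grid_spec))
    return ranges, masks


@dataclass
class DatasetBundle:
    """A fully reproducible synthetic dataset with ground truth."""

    grid: GridSpec
    truth_stack: list[CompositeGrid]
    observed_stack: list[CompositeGrid]
    ranges: list[SpeciesRange]
    masks: list[RangeMask]
    truth_exposure: pd.DataFrame
    nightscape_params: NightscapeParams
    distortion: DistortionSpec
    range_params: RangeParams

    @property
    def years(self) -> list[int]:
        return [g.year for g in self.truth_stack]


def _truth_exposure_table(
    stack: list[CompositeGrid],
    masks: list[RangeMask],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Ground-truth per-species, per-year exposure computed by direct counting.

    Deliberately a separate code path from the exposure module so it can act
    as an oracle for it.
    """
    records = []
    for m in masks:
        for g in stack:
            vals = g.dn[m.rows, m.cols]
            n_lit = int((vals >= threshold).sum())
            records.append(
                {
                    "species_id": m.species_id,
                    "year": g.year,
                    "n_pixels": m.n_pixels,
                    "n_lit": n_lit,
                    "prop_lit": n_lit / m.n_pixels,
                    "mean_dn": float(vals.mean()),
                    "sum_dn": float(vals.sum()),
                }
            )
    cols = ["species_id", "year", "n_pixels", "n_lit", "prop_lit", "mean_dn", "sum_dn"]
    return pd.DataFrame(records, columns=cols)


def make_dataset(
    nightscape_params: NightscapeParams,
    distortion: DistortionSpec | None = None,
    range_params: RangeParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> DatasetBundle:
    """Build a full bundle: truth stack, observed stack, ranges, truth table."""
    if distortion is None:
        distortion = DistortionSpec.identity(nightscape_params.years)
    if range_params is None:
        range_params = RangeParams()
    grid_spec = default_grid_spec(nightscape_params.grid_rows, nightscape_params.grid_cols)
    truth = make_nightscape(nightscape_params, grid_spec)
    observed = [apply_distortion(g, distortion, seed=nightscape_params.seed) for g in truth]
    ranges, masks = make_ranges(range_params, grid_spec)
    truth_table = _truth_exposure_table(truth, masks, threshold=threshold)
    return DatasetBundle(
        grid=grid_spec,
        truth_stack=truth,
        observed_stack=observed,
        ranges=ranges,
        masks=masks,
        truth_exposure=truth_table,
        nightscape_params=nightscape_params,
        distortion=distortion,
        range_params=range_params,
    )


def export_bundle(bundle: DatasetBundle, outdir) -> dict:
    """Write a bundle to disk: per-year GeoTIFFs, GeoJSON ranges, truth CSV.

    Returns a JSON-serializable config block that reproduces the bundle.
    """
    import json
    from pathlib import Path

    from .grids import save_ranges, write_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    (outdir / "observed").mkdir(exist_ok=True)
    for g in bundle.truth_stack:
        write_grid(g, outdir / "truth" / f"dn_{g.year}.tif")
    for g in bundle.observed_stack:
        write_grid(g, outdir / "observed" / f"dn_{g.year}.tif")
    save_ranges(bundle.ranges, outdir / "ranges.geojson")
    bundle.truth_exposure.to_csv(outdir / "truth_exposure.csv", index=False)
    config = {
        "nightscape": {
            k: getattr(bundle.nightscape_params, k)
            for k in NightscapeParams.__dataclass_fields__
        },
        "distortion": {
            "coeffs": {str(y): list(c) for y, c in bundle.distortion.coeffs.items()},
            "noise_sd": bundle.distortion.noise_sd,
        },
        "ranges": {
            k: getattr(bundle.range_params, k) for k in RangeParams.__dataclass_fields__
        },
    }
    (outdir / "bundle_config.json").write_text(json.dumps(config, indent=2))
    return config


def bundle_from_config(config: dict) -> DatasetBundle:
    """Rebuild a bundle from the config block written by :func:`export_bundle`."""
    np_params = NightscapeParams(**{
        **config["nightscape"],
        "seed_col_frac": tuple(config["nightscape"].get("seed_col_frac", (0.0, 1.0))),
    })
    dist = DistortionSpec(
        coeffs={int(y): tuple(c) for y, c in config["distortion"]["coeffs"].items()},
        noise_sd=config["distortion"]["noise_sd"],
    )
    rp = RangeParams(**config["ranges"])
    return make_dataset(np_params, dist, rp)
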