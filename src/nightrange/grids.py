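"""Grids, rasters and range polygons.

Everything downstream operates on a single equal-area grid shared exactly by
all rasters in a stack. Rasters are stored as single-band GeoTIFF-tagged TIFF
files (pixel scale + tiepoint tags, metadata in the image description);
ranges travel as GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .errors import (
    EmptyMaskError,
    GridMismatchError,
    InputError,
    ParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)

DN_MIN = 0.0
DN_MAX = 63.0

#: IUCN Red List codes counted as threatened.
THREATENED_CATEGORIES = frozenset({"CR", "EN", "VU"})

#: The ten broad use categories recognised on range features.
USE_CATEGORIES = (
    "construction",
    "animal_food",
    "human_food",
    "fuel",
    "handicrafts",
    "medicine",
    "household_goods",
    "horticulture",
    "specimen_collection",
    "other",
)

# GeoTIFF tag codes used for georeferencing round-trips.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class GridSpec:
    """A rows x cols equal-area grid.

    ``(origin_x, origin_y)`` is the map coordinate of the *top-left corner* of
    pixel (0, 0); row/col indices are 0-based, map intervals half-open.
    """

    rows: int
    cols: int
    pixel_width: float
    pixel_height: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "ESRI:54017"  # Behrmann equal-area

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ParameterError(f"grid dims must be positive, got {self.rows}x{self.cols}")
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ParameterError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area(self) -> float:
        return self.pixel_width * self.pixel_height

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.rows * self.pixel_height,
            self.origin_x + self.cols * self.pixel_width,
            self.origin_y,
        )

    def pixel_center(self, row: int | np.ndarray, col: int | np.ndarray):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_width
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_height
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing map point (x, y); half-open cells."""
        col = int(math.floor((x - self.origin_x) / self.pixel_width))
        row = int(math.floor((self.origin_y - y) / self.pixel_height))
        return row, col

    def contains_index(self, row: int, col: int) -> bool:
        return 0 <= row < self.rows and 0 <= col < self.cols

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pixel_width": self.pixel_width,
            "pixel_height": self.pixel_height,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class CompositeGrid:
    """One year's composite on a GridSpec; DN real-valued after calibration."""

    year: int
    dn: np.ndarray
    grid: GridSpec
    satellite_label: str | None = None
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn, dtype=float)
        if self.dn.shape != self.grid.shape:
            raise GridMismatchError(
                f"dn shape {self.dn.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean array of non-nodata pixels."""
        if math.isnan(self.nodata):
            return ~np.isnan(self.dn)
        return self.dn != self.nodata

    def copy_with(self, **kwargs) -> "CompositeGrid":
        out = replace(self, **kwargs)
        return out


@dataclass(frozen=True)
class SpeciesRange:
    """A species' range polygon plus Red List attributes."""

    species_id: str
    name: str
    geometry: BaseGeometry
    category: str = "LC"
    used: bool = False
    use_categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise InputError(f"empty geometry for species {self.species_id!r}")

    @property
    def threatened(self) -> bool:
        return self.category in THREATENED_CATEGORIES


@dataclass
class RangeMask:
    """A species' range as a pixel index set on a GridSpec."""

    species_id: str
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.rows.shape != self.cols.shape:
            raise InputError("rows/cols index arrays must align")
        if self.rows.size < 1:
            raise EmptyMaskError(f"mask for {self.species_id!r} has no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def values(self, grid: CompositeGrid) -> np.ndarray:
        """DN values of the composite at the mask pixels."""
        if not self.in_grid(grid.grid):
            raise GridMismatchError(f"mask {self.species_id!r} falls outside grid")
        return grid.dn[self.rows, self.cols]

    def in_grid(self, grid: GridSpec) -> bool:
        return bool(
            (self.rows >= 0).all()
            and (self.rows < grid.rows).all()
            and (self.cols >= 0).all()
            and (self.cols < grid.cols).all()
        )


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def write_grid(grid: CompositeGrid, path: str | Path, dtype: str = "float32") -> Path:
    """Write a composite as a single-band TIFF with GeoTIFF georeferencing tags."""
    path = Path(path)
    meta = {
        "year": grid.year,
        "satellite_label": grid.satellite_label,
        "nodata": None if math.isnan(grid.nodata) else grid.nodata,
        "grid": grid.grid.to_dict(),
    }
    spec = grid.grid
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.pixel_width, spec.pixel_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
    ]
    tifffile.imwrite(
        path,
        grid.dn.astype(dtype),
        description=json.dumps(meta),
        extratags=extratags,
    )
    return path


def read_grid(path: str | Path, year: int | None = None) -> CompositeGrid:
    """Read a single-band TIFF written by :func:`write_grid`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        dn = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    grid_dict = meta.get("grid")
    if grid_dict is None:
        raise InputError(f"{path} carries no grid metadata")
    spec = GridSpec.from_dict(grid_dict)
    nodata = meta.get("nodata")
    nodata = float("nan") if nodata is None else float(nodata)
    out = CompositeGrid(
        year=int(year if year is not None else meta["year"]),
        dn=dn,
        grid=spec,
        satellite_label=meta.get("satellite_label"),
        nodata=nodata,
    )
    return out


def read_stack(
    paths: Sequence[str | Path], years: Sequence[int] | None = None
) -> list[CompositeGrid]:
    """Read one raster per year into a year-ordered stack on one shared GridSpec.

    DN values outside [0, 63] are clipped with a warning; mismatched grids
    raise :class:`GridMismatchError`.
    """
    if years is not None and len(years) != len(paths):
        raise InputError("paths and years must align one-to-one")
    grids = []
    for i, p in enumerate(paths):
        g = read_grid(p, year=None if years is None else years[i])
        valid = g.valid_mask
        vals = g.dn[valid]
        if vals.size and (vals.min() < DN_MIN or vals.max() > DN_MAX):
            warnings.warn(
                f"{p}: DN outside [0, 63] clipped (range {vals.min():.2f}..{vals.max():.2f})",
                stacklevel=2,
            )
            g.dn[valid] = np.clip(vals, DN_MIN, DN_MAX)
        grids.append(g)
    if not grids:
        raise InputError("no rasters given")
    ref = grids[0].grid
    for g in grids[1:]:
        if g.grid != ref:
            raise GridMismatchError(
                f"raster for year {g.year} is on a different grid than year {grids[0].year}"
            )
    grids.sort(key=lambda g: g.year)
    yrs = [g.year for g in grids]
    if len(set(yrs)) != len(yrs):
        raise InputError(f"duplicate years in stack: {yrs}")
    return grids


# ---------------------------------------------------------------------------
# Vector I/O
# ---------------------------------------------------------------------------

def save_ranges(ranges: Iterable[SpeciesRange], path: str | Path) -> Path:
    """Write ranges as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = []
    for r in ranges:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {
                    "species_id": r.species_id,
                    "name": r.name,
                    "category": r.category,
                    "used": bool(r.used),
                    "use_categories": list(r.use_categories),
                },
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def load_ranges(path: str | Path, repair: bool = True) -> list[SpeciesRange]:
    """Load a GeoJSON FeatureCollection of species ranges.

    Invalid geometries are repaired (``make_valid``) when ``repair`` is true,
    otherwise rejected; empty geometries are always rejected with the species
    id logged. Duplicate species ids raise :class:`InputError`.
    """
    doc = json.loads(Path(path).read_text())
    out: list[SpeciesRange] = []
    seen: set[str] = set()
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        for key in ("species_id", "category", "used"):
            if key not in props:
                raise SchemaError(f"feature missing required property {key!r}")
        sid = str(props["species_id"])
        geom_json = feat.get("geometry")
        geom = shape(geom_json) if geom_json else None
        if geom is None or geom.is_empty:
            logger.warning("rejecting species %s: empty geometry", sid)
            continue
        if not geom.is_valid:
            if not repair:
                logger.warning("rejecting species %s: invalid geometry", sid)
                continue
            geom = make_valid(geom)
            if geom.is_empty:
                logger.warning("rejecting species %s: geometry unrepairable", sid)
                continue
        if sid in seen:
            raise InputError(f"duplicate species_id {sid!r}")
        seen.add(sid)
        out.append(
            SpeciesRange(
                species_id=sid,
                name=str(props.get("name", sid)),
                geometry=geom,
                category=str(props["category"]),
                used=bool(props["used"]),
                use_categories=tuple(props.get("use_categories") or ()),
            )
        )
    return out


def save_masks(masks: Iterable[RangeMask], path: str | Path) -> Path:
    """Export masks as CSV rows of (species_id, row, col)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_id,row,col\n")
        for m in masks:
            for r, c in zip(m.rows.tolist(), m.cols.tolist()):
                fh.write(f"{m.species_id},{r},{c}\n")
    return path


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_range(species_range: SpeciesRange, grid: GridSpec) -> RangeMask:
    """Rasterize a range polygon with the pixel-center-in-polygon rule.

    A pixel belongs to the mask when its center lies inside (or on the
    boundary of) the geometry. If no pixel center qualifies, the single pixel
    containing the geometry centroid is assigned, guaranteeing n_pixels >= 1.
    """
    geom = species_range.geometry
    xmin, ymin, xmax, ymax = geom.bounds
    gxmin, gymin, gxmax, gymax = grid.bounds
    if xmax < gxmin or xmin > gxmax or ymax < gymin or ymin > gymax:
        raise EmptyMaskError(
            f"geometry of {species_range.species_id!r} lies outside the grid extent"
        )
    # candidate window of pixels whose centers could fall in the bbox
    c0 = max(0, int(math.floor((xmin - grid.origin_x) / grid.pixel_width - 0.5)))
    c1 = min(grid.cols - 1, int(math.ceil((xmax - grid.origin_x) / grid.pixel_width - 0.5)))
    r0 = max(0, int(math.floor((grid.origin_y - ymax) / grid.pixel_height - 0.5)))
    r1 = min(grid.rows - 1, int(math.ceil((grid.origin_y - ymin) / grid.pixel_height - 0.5)))
    rows_sel: np.ndarray
    cols_sel: np.ndarray
    if c1 >= c0 and r1 >= r0:
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        xs, ys = grid.pixel_center(rr.ravel(), cc.ravel())
        inside = shapely.covers(geom, shapely.points(xs, ys))
        rows_sel = rr.ravel()[inside]
        cols_sel = cc.ravel()[inside]
    else:
        rows_sel = np.empty(0, dtype=np.int64)
        cols_sel = np.empty(0, dtype=np.int64)
    if rows_sel.size == 0:
        cen = geom.centroid
        row, col = grid.index_of(cen.x, cen.y)
        if not grid.contains_index(row, col):
            raise EmptyMaskError(
                f"centroid of {species_range.species_id!r} falls outside the grid"
            )
        rows_sel = np.array([row], dtype=np.int64)
        cols_sel = np.array([col], dtype=np.int64)
    return RangeMask(species_id=species_range.species_id, rows=rows_sel, cols=cols_sel)


def rasterize_all(
    ranges: Sequence[SpeciesRange], grid: GridSpec, skip_empty: bool = False
) -> list[RangeMask]:
    """Rasterize many ranges; optionally skip (and log) off-grid geometries."""
    masks = []
    for r in ranges:
        try:
            masks.append(rasterize_range(r, grid))
        except EmptyMaskError:
            if not skip_empty:
                raise
            logger.warning("species %s produced no pixels; skipped", r.species_id)
    return masks
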