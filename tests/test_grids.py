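import json
import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

from nightrange.errors import (
    EmptyMaskError,
    GridMismatchError,
    InputError,
    ParameterError,
    SchemaError,
)
from nightrange.grids import (
    CompositeGrid,
    GridSpec,
    RangeMask,
    SpeciesRange,
    load_ranges,
    rasterize_range,
    read_grid,
    read_stack,
    save_masks,
    save_ranges,
    write_grid,
)


class TestGridSpec:
    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ParameterError):
            GridSpec(rows=0, cols=10, pixel_width=1, pixel_height=1)
        with pytest.raises(ParameterError):
            GridSpec(rows=10, cols=10, pixel_width=-1, pixel_height=1)

    def test_pixel_center_and_index_roundtrip(self, unit_grid):
        x, y = unit_grid.pixel_center(3, 5)
        assert (x, y) == (5.5, 60.5)
        assert unit_grid.index_of(x, y) == (3, 5)

    def test_pixel_area(self):
        g = GridSpec(rows=4, cols=4, pixel_width=811.0, pixel_height=811.0)
        assert g.pixel_area == pytest.approx(811.0 * 811.0)

    def test_dict_roundtrip(self, unit_grid):
        assert GridSpec.from_dict(unit_grid.to_dict()) == unit_grid


class TestRasterIO:
    def test_write_read_roundtrip(self, tmp_path, unit_grid):
        rng = np.random.default_rng(0)
        dn = rng.uniform(0, 63, unit_grid.shape).astype(np.float32).astype(float)
        g = CompositeGrid(year=1999, dn=dn, grid=unit_grid, satellite_label="F10")
        p = write_grid(g, tmp_path / "g.tif")
        back = read_grid(p)
        assert back.year == 1999
        assert back.satellite_label == "F10"
        assert back.grid == unit_grid
        np.testing.assert_array_equal(back.dn, dn)

    def test_read_stack_orders_years(self, tmp_path, unit_grid, grid_factory):
        paths = []
        for year in (2001, 1999, 2000):
            p = tmp_path / f"{year}.tif"
            write_grid(grid_factory(1.0, year=year), p)
            paths.append(p)
        stack = read_stack(paths)
        assert [g.year for g in stack] == [1999, 2000, 2001]

    def test_single_file_stack_accepted(self, tmp_path, grid_factory):
        p = tmp_path / "one.tif"
        write_grid(grid_factory(2.0, year=1992), p)
        assert len(read_stack([p])) == 1

    def test_grid_mismatch_rejected(self, tmp_path, unit_grid, grid_factory):
        other = GridSpec(rows=64, cols=64, pixel_width=2.0, pixel_height=2.0,
                         origin_x=0.0, origin_y=128.0)
        write_grid(grid_factory(1.0, year=2000), tmp_path / "a.tif")
        write_grid(grid_factory(1.0, year=2001, grid=other), tmp_path / "b.tif")
        with pytest.raises(GridMismatchError):
            read_stack([tmp_path / "a.tif", tmp_path / "b.tif"])

    def test_out_of_range_dn_clipped_with_warning(self, tmp_path, unit_grid):
        dn = np.full(unit_grid.shape, 70.0)
        g = CompositeGrid(year=2000, dn=dn, grid=unit_grid)
        p = write_grid(g, tmp_path / "hot.tif")
        with pytest.warns(UserWarning, match="clipped"):
            (back,) = read_stack([p])
        assert back.dn.max() == 63.0


class TestVectorIO:
    def _ranges(self):
        return [
            SpeciesRange("SPA", "A", box(1, 1, 5, 5), category="EN", used=True,
                         use_categories=("fuel", "medicine")),
            SpeciesRange("SPB", "B", Point(10, 10).buffer(2.0), category="LC", used=False),
        ]

    def test_geojson_roundtrip(self, tmp_path):
        p = save_ranges(self._ranges(), tmp_path / "r.geojson")
        back = load_ranges(p)
        assert [r.species_id for r in back] == ["SPA", "SPB"]
        assert back[0].category == "EN" and back[0].threatened
        assert not back[1].threatened
        assert back[0].used and not back[1].used
        assert back[0].use_categories == ("fuel", "medicine")
        assert back[0].geometry.equals(box(1, 1, 5, 5))

    def test_threatened_derivation(self):
        for cat, expect in [("CR", True), ("EN", True), ("VU", True),
                            ("NT", False), ("LC", False), ("DD", False)]:
            r = SpeciesRange("X", "x", box(0, 0, 1, 1), category=cat)
            assert r.threatened is expect

    def test_empty_geometry_rejected_and_logged(self, tmp_path, caplog):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": None,
                 "properties": {"species_id": "GONE", "category": "LC", "used": False}},
            ],
        }
        p = tmp_path / "empty.geojson"
        p.write_text(json.dumps(doc))
        with caplog.at_level("WARNING"):
            out = load_ranges(p)
        assert out == []
        assert "GONE" in caplog.text

    def test_missing_property_is_schema_error(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature",
                 "geometry": {"type": "Point", "coordinates": [0, 0]},
                 "properties": {"species_id": "X"}},
            ],
        }
        p = tmp_path / "bad.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            load_ranges(p)

    def test_duplicate_id_rejected(self, tmp_path):
        rs = self._ranges()
        rs.append(SpeciesRange("SPA", "dup", box(0, 0, 1, 1)))
        p = save_ranges(rs, tmp_path / "dup.geojson")
        with pytest.raises(InputError):
            load_ranges(p)

    def test_mask_csv_export(self, tmp_path):
        m = RangeMask("SPX", rows=[1, 2], cols=[3, 4])
        p = save_masks([m], tmp_path / "m.csv")
        lines = p.read_text().strip().splitlines()
        assert lines == ["species_id,row,col", "SPX,1,3", "SPX,2,4"]


class TestRasterize:
    def test_exact_block(self, unit_grid):
        # rectangle covering exactly a 3-row x 4-col pixel block
        geom = box(2.0, 58.0, 6.0, 61.0)
        mask = rasterize_range(SpeciesRange("S", "s", geom), unit_grid)
        assert mask.n_pixels == 12
        assert mask.pixels == {(r, c) for r in (3, 4, 5) for c in (2, 3, 4, 5)}

    def test_subpixel_polygon_gets_centroid_pixel(self, unit_grid):
        geom = box(10.1, 53.1, 10.3, 53.3)  # far from any pixel center
        mask = rasterize_range(SpeciesRange("S", "s", geom), unit_grid)
        assert mask.n_pixels == 1
        assert mask.pixels == {unit_grid.index_of(10.2, 53.2)}

    def test_outside_grid_raises(self, unit_grid):
        geom = box(1000, 1000, 1001, 1001)
        with pytest.raises(EmptyMaskError):
            rasterize_range(SpeciesRange("S", "s", geom), unit_grid)

    @staticmethod
    def _oracle_pixels(geom, grid):
        """Exhaustive scalar center-in-polygon check over the whole grid."""
        hits = set()
        for r in range(grid.rows):
            for c in range(grid.cols):
                x, y = grid.pixel_center(r, c)
                if geom.covers(Point(float(x), float(y))):
                    hits.add((r, c))
        return hits

    def test_l_shape_matches_exhaustive_oracle(self, unit_grid):
        l_shape = Polygon([(5, 40), (15, 40), (15, 44), (9, 44), (9, 52), (5, 52)])
        mask = rasterize_range(SpeciesRange("L", "l", l_shape), unit_grid)
        assert mask.pixels == self._oracle_pixels(l_shape, unit_grid)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_polygons_match_oracle(self, unit_grid, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(5, 59, size=(6, 2))
        geom = shapely.convex_hull(shapely.multipoints(pts))
        mask = rasterize_range(SpeciesRange("R", "r", geom), unit_grid)
        oracle = self._oracle_pixels(geom, unit_grid)
        assert mask.pixels == (oracle or mask.pixels)  # centroid fallback if empty
        if oracle:
            assert mask.pixels == oracle

    def test_area_consistency_convex(self, unit_grid):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pts = rng.uniform(5, 59, size=(8, 2))
            geom = shapely.convex_hull(shapely.multipoints(pts))
            mask = rasterize_range(SpeciesRange("A", "a", geom), unit_grid)
            band = geom.length * max(unit_grid.pixel_width, unit_grid.pixel_height)
            assert abs(mask.n_pixels * unit_grid.pixel_area - geom.area) <= band


class TestRangeMask:
    def test_requires_pixels(self):
        with pytest.raises(EmptyMaskError):
            RangeMask("S", rows=[], cols=[])

    def test_values_requires_in_grid(self, unit_grid, grid_factory):
        m = RangeMask("S", rows=[100], cols=[0])
        with pytest.raises(GridMismatchError):
            m.values(grid_factory(1.0))
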