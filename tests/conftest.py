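import numpy as np
import pytest

from nightrange.grids import CompositeGrid, GridSpec
from nightrange.synthetic import (
    DistortionSpec,
    NightscapeParams,
    RangeParams,
    make_dataset,
)


@pytest.fixture
def unit_grid() -> GridSpec:
    """64x64 grid with 1-unit pixels, origin at top-left (0, 64)."""
    return GridSpec(rows=64, cols=64, pixel_width=1.0, pixel_height=1.0,
                    origin_x=0.0, origin_y=64.0)


@pytest.fixture
def grid_factory(unit_grid):
    """Build a CompositeGrid on the unit grid from a value array or scalar."""

    def make(values, year=2000, grid=None):
        grid = grid or unit_grid
        if np.isscalar(values):
            values = np.full(grid.shape, float(values))
        return CompositeGrid(year=year, dn=np.asarray(values, dtype=float), grid=grid)

    return make


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across tests."""
    np_params = NightscapeParams(
        grid_rows=64, grid_cols=96, n_years=7, n_urban_seeds=10,
        growth_rate=0.08, base_brightness_decay=6.0, noise_sd=0.0, seed=11,
    )
    dist = DistortionSpec.random(np_params.years, seed=12, noise_sd=0.4)
    rp = RangeParams(n_species=60, range_size_min=1, range_size_max=400, seed=13)
    return make_dataset(np_params, dist, rp)
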