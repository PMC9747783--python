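import numpy as np
import pytest
from hypothesis import settings

import forestdebt as fd

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid() -> fd.GridSpec:
    """A 10x10-cell 0.5-degree window near the equator."""
    return fd.GridSpec(-5.0, 0.0, -2.5, 2.5, 0.5)


@pytest.fixture(scope="session")
def default_world() -> fd.SyntheticWorld:
    """One default synthetic world shared by read-only tests."""
    return fd.generate_world(fd.SyntheticWorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_stack(default_world):
    records = fd.filter_forest_dwelling(default_world.species)
    return fd.rasterize_and_stack(records, default_world.grid)


def constant_cover_series(grid: fd.GridSpec, years, forest: float = 0.5,
                          grass: float = 0.2) -> fd.LandCoverSeries:
    """A time-constant cover series with the given forest/grassland split.

    The non-natural remainder is split 20/20/10/50 between cropland, pasture,
    urban and "other", so any forest + grass <= 1 is a valid closure.
    """
    years = np.asarray(years)
    residual = 1.0 - forest - grass
    assert residual >= 0
    base = np.array([forest, grass, 0.2 * residual, 0.2 * residual,
                     0.1 * residual, 0.5 * residual])
    cover = np.tile(base[None, :, None], (len(years), 1, grid.n_cells))
    return fd.LandCoverSeries(grid, years, cover)
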