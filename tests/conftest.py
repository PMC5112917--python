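import numpy as np
import pytest

from moltrace import (
    IsotopeGrid,
    SimulationConfig,
    make_precip_isoscape,
    sample_sites,
    simulate_feathers,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Coarse study-extent config: fast enough for per-test simulation."""
    return SimulationConfig(seed=11, grid_shape=(40, 48))


@pytest.fixture(scope="session")
def small_world(small_config):
    """(config, precip, sd, sites, birds) shared across read-only tests."""
    precip, sd = make_precip_isoscape(small_config)
    sites = sample_sites(small_config, 30)
    birds = simulate_feathers(small_config, sites, 8, precip)
    return small_config, precip, sd, sites, birds


@pytest.fixture()
def plane_grid() -> IsotopeGrid:
    """Deterministic planar grid: value = -50 - 2*(lat-40) + 1.5*(lon+100)."""
    grid = IsotopeGrid(np.zeros((20, 25)), origin_lon=-102.0, origin_lat=44.0, cell_size=0.4)
    lats, lons = grid.cell_centers()
    grid.values = -50.0 - 2.0 * (lats[:, None] - 40.0) + 1.5 * (lons[None, :] + 100.0)
    return grid
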