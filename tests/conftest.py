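import numpy as np
import pytest

import thermodiv as td
from thermodiv.synthetic_paleoclimate import REGION_NAMES, ClimateField, GridSpec


@pytest.fixture(scope="session")
def default_pool():
    return td.generate_niche_pool()


@pytest.fixture(scope="session")
def toy_pool():
    """3-niche pool [0,1], [1,2], [0,2] (breadth-major order)."""
    return td.generate_niche_pool(
        td.NichePoolSpec(t_min=0.0, t_max=2.0, breadth_min=1.0,
                         breadth_max=2.0, grid_increment=1.0))


@pytest.fixture(scope="session")
def proxy_scenario():
    return td.build_scenario("proxy-cooling")


def make_uniform_field(temperature, n_lat=8, n_lon=8, shelf_cells=None,
                       cell_temps=None, scenario="custom"):
    """A hand-built climate field: all-ocean grid, shelf on selected cells.

    ``shelf_cells`` is a list of (i, j) indices; ``cell_temps`` optionally
    overrides the uniform temperature on those cells.
    """
    grid = GridSpec(n_lat=n_lat, n_lon=n_lon)
    temp = np.full(grid.shape, float(temperature))
    shelf = np.zeros(grid.shape, dtype=bool)
    if shelf_cells is None:
        shelf[:] = True
    else:
        for k, (i, j) in enumerate(shelf_cells):
            shelf[i, j] = True
            if cell_temps is not None:
                temp[i, j] = cell_temps[k]
    return ClimateField(
        grid=grid, age=460.0, temperature=np.maximum(temp, -1.8),
        land_mask=np.zeros(grid.shape, dtype=bool), shelf_mask=shelf,
        region_codes=np.zeros(grid.shape, dtype=np.int8),
        scenario=scenario, region_names=REGION_NAMES,
    )
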