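import datetime as dt

import numpy as np
import pytest

from envgrid import crs
from envgrid.grids import GridSpec, RasterLayer
from envgrid.synth import FixtureConfig, make_dem, make_lst_scene


@pytest.fixture
def small_grid():
    return GridSpec(crs.UTM32N, 640_000.0, 5_160_000.0, 200.0, 8, 8)


@pytest.fixture
def config():
    # Small tile so the full chain runs in seconds.
    return FixtureConfig(seed=7, dem_shape=(40, 40), ms_shape=(120, 120), n_stations=30)


@pytest.fixture
def dem(config):
    return make_dem(config)


@pytest.fixture
def lst_scene(config, dem):
    return make_lst_scene(config, dem, dt.date(2020, 7, 1))


def layer_on(grid, values, mask=None, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return RasterLayer(grid=grid, values=values, nodata_mask=np.asarray(mask, bool), **kw)


@pytest.fixture
def make_layer():
    return layer_on
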