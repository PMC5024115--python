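import datetime as dt

import numpy as np
import pytest

from reefwatch.grid import Grid
from reefwatch.series import BANDS, SceneObservation, SceneSeries


@pytest.fixture
def small_grid() -> Grid:
    # ~20x20 pixels at 250 m
    return Grid(lat_min=10.0, lat_max=10.0449, lon_min=115.0, lon_max=115.0449)


@pytest.fixture
def tiny_grid() -> Grid:
    # ~8x8 pixels
    return Grid(lat_min=10.0, lat_max=10.01797, lon_min=115.0, lon_max=115.01797)


def make_observation(grid, values, cloud=None, date=dt.date(2015, 1, 1)):
    """Uniform-band observation; ``values`` maps wavelength to scalar or array."""
    bands = {}
    for wl in BANDS:
        v = values.get(wl, 0.0)
        bands[wl] = np.full(grid.shape, v, dtype=float) if np.isscalar(v) else np.asarray(v, dtype=float)
    return SceneObservation(date=date, bands=bands, cloud=cloud, grid=grid)


def make_series(grid, dates, band_stacks, cloud=None):
    T = len(dates)
    bands = {}
    for wl in BANDS:
        arr = band_stacks.get(wl)
        if arr is None:
            arr = np.zeros((T, *grid.shape))
        bands[wl] = np.asarray(arr, dtype=float)
    if cloud is None:
        cloud = np.zeros((T, *grid.shape), dtype=bool)
    return SceneSeries(grid=grid, dates=tuple(dates), bands=bands, cloud=np.asarray(cloud, dtype=bool))


@pytest.fixture
def obs_factory():
    return make_observation


@pytest.fixture
def series_factory():
    return make_series
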