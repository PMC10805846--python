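"""Shared synthetic-world fixtures.

Session-scoped so the expensive world generation happens once; tests must
not mutate fixture objects in place.
"""

import numpy as np
import pandas as pd
import pytest

import understory as u
from understory.features import extract_at_points
from understory.harmonize import harmonize_network


EXTENT = (-2.0, -1.0, 20.0, 21.0)   # 1°x1° block in the Congo basin latitudes


@pytest.fixture(scope="session")
def stack():
    """100x100 predictor stack over a 1°x1° tropical block."""
    return u.generate_predictor_stack(EXTENT, 0.01, seed=11)


@pytest.fixture(scope="session")
def network(stack):
    return u.sample_sensor_network(stack, 150, seed=12)


def _table(stack, network, params, months=6, scale="daily"):
    series = u.generate_logger_series(network, stack, params, "2020-01-01", months)
    obs = {sid: df[["timestamp_utc", "t_air_c"]] for sid, df in series.items()}
    monthly = harmonize_network(obs, network)
    return extract_at_points(stack, network, monthly, scale)


@pytest.fixture(scope="session")
def noiseless_table(stack, network):
    """Training table from a noise-free world: response is an exact function
    of the predictors."""
    params = u.GenerativeParams(noise_sd=0.0, spatial_sill=0.0, seed=13)
    return _table(stack, network, params)


@pytest.fixture(scope="session")
def noisy_table(stack, network):
    """Training table with sensor-month noise of sd 0.5 °C that is
    unpredictable from the predictors (short-range correlated field plus
    15-min instrument noise that averages out in monthly means)."""
    params = u.GenerativeParams(noise_sd=0.3, spatial_sill=0.25, spatial_range=2.0, seed=14)
    return _table(stack, network, params)


@pytest.fixture(scope="session")
def generative_defaults():
    return u.GenerativeParams()


@pytest.fixture
def uniform_stack():
    """Tiny hand-built stack with spatially constant fields (elevation apart),
    for examples that need 'all else equal'."""
    from understory.grids import Grid
    from understory.synthetic import PredictorStack
    grid = Grid(nrows=2, ncols=2, lat_min=-1.0, lon_min=20.0, cell_size=0.5)
    shp = grid.shape
    hours = np.arange(24)
    diurnal = 4.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    macro_t = np.broadcast_to((25.0 + diurnal)[None, :, None, None], (12, 24) + shp).copy()
    elev = np.array([[0.0, 1000.0], [500.0, 1500.0]])
    stk = PredictorStack(
        grid=grid, elevation=elev,
        slope=np.zeros(shp), aspect=np.zeros(shp),
        lai=np.full(shp, 4.0), fapar=np.full(shp, 0.6),
        canopy_height=np.full(shp, 18.0), tcc=np.full(shp, 80.0),
        macro_t=macro_t,
        macro_precip=np.full((12,) + shp, 150.0),
        macro_rad=np.full((12,) + shp, 1.5e7),
    )
    stk.validate()
    return stk
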