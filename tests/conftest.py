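import numpy as np
import pytest

from socdev import ModelParams, SpikeRaster
from socdev.fixtures import branching_raster, poisson_raster


def small_params(**overrides):
    """Compact network used across model tests (fast to simulate)."""
    kw = dict(
        ca_target=5.0, n_neurons=25, grid_rows=5, grid_cols=5,
        grid_spacing=4.0, init_a=3.0, seed=0,
    )
    kw.update(overrides)
    return ModelParams(**kw)


@pytest.fixture
def params():
    return small_params()


@pytest.fixture(scope="session")
def poisson_fix():
    """59-unit homogeneous Poisson raster (null model)."""
    return poisson_raster(59, rate_per_unit=0.02, duration=2e5, seed=7)


@pytest.fixture(scope="session")
def critical_fix():
    """Critical branching raster (sigma = 1), ~4e3 cascades."""
    return branching_raster(59, 1.0, drive_rate=0.002, duration=2e6, seed=7)


def raster_from_times(times, n_units=2, units=None, **kw):
    times = np.asarray(times, dtype=float)
    if units is None:
        units = np.arange(times.size) % n_units
    return SpikeRaster(times=times, units=np.asarray(units), n_units=n_units,
                       **kw)
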