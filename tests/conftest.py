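import logging

import numpy as np
import pytest
import xarray as xr
from hypothesis import HealthCheck, settings

from gppshift import SyntheticConfig

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Scan warnings about degenerate windows/ties are expected in edge-case tests.
logging.getLogger("gppshift.lepage").setLevel(logging.ERROR)
logging.getLogger("gppshift.factorial").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def coarse_config():
    """Default study conditions on a 2-degree grid (fast for unit tests)."""
    cfg = SyntheticConfig()
    cfg.grid.resolution = 2.0
    cfg.smoothing_cells = 1.0
    return cfg


def make_field(values, years=None, lat=None, lon=None, units="gC m-2 month-1",
               name="gpp", time=None):
    """Small annual or monthly gridded field for tests."""
    values = np.asarray(values, dtype=float)
    if lat is None:
        lat = np.arange(values.shape[1], dtype=float) + 30.0
    if lon is None:
        lon = np.arange(values.shape[2], dtype=float) + 100.0
    if time is not None:
        coords = {"time": time, "lat": lat, "lon": lon}
        dims = ("time", "lat", "lon")
    else:
        if years is None:
            years = np.arange(2000, 2000 + values.shape[0])
        coords = {"year": years, "lat": lat, "lon": lon}
        dims = ("year", "lat", "lon")
    return xr.DataArray(values, coords=coords, dims=dims, name=name,
                        attrs={"units": units})


@pytest.fixture
def field_factory():
    return make_field
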