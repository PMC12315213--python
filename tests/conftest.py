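import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import agroclim as ac
from agroclim.climate import VARIABLES, DailyClimateSeries

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_series(
    start_year=2000,
    n_years=2,
    tmin=10.0,
    tmax=20.0,
    precip=0.0,
    radiation=15.0,
    rel_humidity=70.0,
    wind=3.0,
    cell_id="test",
    latitude=-41.0,
    **overrides,
) -> DailyClimateSeries:
    """Constant-weather series; per-variable overrides may be arrays."""
    index = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D")
    base = dict(tmin=tmin, tmax=tmax, precip=precip, radiation=radiation,
                rel_humidity=rel_humidity, wind=wind)
    data = {}
    for var in VARIABLES:
        value = overrides.get(var, base[var])
        data[var] = np.broadcast_to(np.asarray(value, float), len(index)).copy()
    return DailyClimateSeries(
        cell_id=cell_id, latitude=latitude, data=pd.DataFrame(data, index=index)
    )


@pytest.fixture(scope="session")
def gen_config():
    """Small 2x2 synthetic grid, 6 years."""
    return ac.WeatherGenConfig.grid(seed=11, n_years=6, nx=2, ny=2,
                                    start_year=2000)


@pytest.fixture(scope="session")
def baseline_series(gen_config):
    return ac.generate_series(
        gen_config, ac.ScenarioPerturbation.baseline(), "r0c0"
    )


@pytest.fixture(scope="session")
def cool_series():
    """A single cool southern cell, 22 years, for phenology experiments."""
    cfg = ac.WeatherGenConfig.grid(
        seed=23, n_years=22, nx=1, ny=1, lat_min=-44.5, lat_max=-44.5,
        start_year=1995,
    )
    return ac.generate_series(cfg, ac.ScenarioPerturbation.baseline(), "r0c0")
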