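import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/reference.py importable

from dynagrass import config as cfg
from dynagrass.plant import PlantParams
from dynagrass.weather import GeneratorStats


@pytest.fixture(scope="session")
def params() -> PlantParams:
    return cfg.default_plant_params()


@pytest.fixture(scope="session")
def profile():
    return cfg.default_soil_profile()


@pytest.fixture(scope="session")
def gen_stats() -> GeneratorStats:
    return cfg.default_generator_stats()


def make_synthetic_series(years=3, start=2011, rain_mm=8.9, summer_scale=1.0,
                          delta_t=0.0) -> pd.DataFrame:
    """Deterministic pre-alpine-like forcing: sinusoidal temperature and
    radiation, rain every third day (optionally scaled May-September)."""
    rows = []
    for d in pd.date_range(f"{start}-01-01", f"{start + years - 1}-12-31", freq="D"):
        doy = d.dayofyear
        tmean = 7.0 - 12.0 * np.cos(2 * np.pi * (doy - 15) / 365.25) + delta_t
        rad = max(20.0, 150.0 - 120.0 * np.cos(2 * np.pi * (doy - 10) / 365.25))
        p = rain_mm if doy % 3 == 0 else 0.0
        if 5 <= d.month <= 9:
            p *= summer_scale
        rows.append((d, tmean - 5.0, tmean + 5.0, p, rad))
    return pd.DataFrame(rows, columns=["date", "tmin", "tmax", "precip", "rad"])


@pytest.fixture(scope="session")
def synthetic_series():
    return make_synthetic_series
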