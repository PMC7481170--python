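import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ecoforce.synthetic_weather import SyntheticClimateSpec, gen_station_obs


@pytest.fixture(scope="session")
def obs_3yr() -> pd.DataFrame:
    """Three years of synthetic station observations, fixed seed."""
    return gen_station_obs(SyntheticClimateSpec(seed=7, n_years=3))


@pytest.fixture(scope="session")
def obs_spec() -> SyntheticClimateSpec:
    return SyntheticClimateSpec(seed=7, n_years=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_daily_series(rng, n_years=1, start_year=2001, kind="temperature"):
    """A random but physically plausible daily series for oracle checks."""
    index = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31")
    if kind == "temperature":
        values = rng.normal(10.0, 6.0, len(index))
    else:  # precipitation: zero-inflated
        values = np.where(rng.random(len(index)) < 0.5, 0.0,
                          rng.gamma(0.8, 5.0, len(index)))
    return pd.Series(values, index=index)
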