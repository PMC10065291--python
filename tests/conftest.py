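import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import heatlag as hl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim() -> hl.SimConfig:
    """A two-year, small-cohort world that keeps unit tests fast."""
    return hl.SimConfig(
        n_stations=6,
        n_subjects=300,
        years=(2012, 2013),
        missing_rate=0.0,
        baseline_daily_hazard=4e-3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_sim):
    """Prepared inputs (exposure, heat waves, deaths) for the small world."""
    from heatlag import exposure, pipeline

    cfg = pipeline.RunConfig(
        sim=small_sim,
        percentiles=(90.0,),
        idw_params=exposure.IdwParams(2.0, small_sim.n_stations),
    )
    return cfg, pipeline.prepare(cfg)


@pytest.fixture()
def daily_calendar():
    return pd.date_range("2014-01-01", periods=365, freq="D")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
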