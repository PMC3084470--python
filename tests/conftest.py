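import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chemprior.config import FateParameters, ThresholdConfig
from chemprior.fate import HalfLifeSet
from chemprior.substances import PropertySet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def thresholds():
    return ThresholdConfig()


@pytest.fixture
def fate_params():
    return FateParameters()


@pytest.fixture
def basic_props():
    """A well-characterised, moderately persistent substance."""
    return PropertySet(mw=300.0, log_kow=5.0, log_kaw=-3.0,
                       t_half_water=300.0, t_half_air=100.0)


def random_fate_inputs(rng: np.random.Generator):
    """One randomized (properties, half-lives, environment) triple."""
    props = PropertySet(
        mw=float(rng.uniform(80, 600)),
        log_kow=float(rng.uniform(0, 8)),
        log_kaw=float(rng.uniform(-10, 1)),
    )
    hl = HalfLifeSet(
        water=float(10 ** rng.uniform(-0.5, 3.5)),
        sediment=float(10 ** rng.uniform(-0.5, 3.5)),
        soil=float(10 ** rng.uniform(-0.5, 3.5)),
        air=float(10 ** rng.uniform(-1.5, 2.5)),
    )
    params = FateParameters(
        u_air_water=float(30 * 10 ** rng.uniform(-1, 1)),
        u_air_soil=float(30 * 10 ** rng.uniform(-1, 1)),
        u_water_air=float(0.05 * 10 ** rng.uniform(-1, 1)),
        u_soil_water=float(1e-4 * 10 ** rng.uniform(-1, 1)),
        u_soil_air=float(0.02 * 10 ** rng.uniform(-1, 1)),
    )
    return props, hl, params
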