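import numpy as np
import pytest

from wprime_kinetics.datamodel import AthleteProfile, PowerTimeSeries
from wprime_kinetics.synthetic import SimulationConfig, simulate_athlete


@pytest.fixture
def athlete() -> AthleteProfile:
    """Deterministic mid-cohort athlete with round reference numbers."""
    return AthleteProfile(
        id="fixture", age=32.0, sex="male", body_mass=70.0, height=1.77,
        cp_watts=274.0, w_prime=14800.0, vo2max=57.5,
        vo2_at_cp=46.6, vo2_at_get=37.4,
        hr_max=184.0, hr_cp=170.0, hr_get=141.0)


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Noise-free generator configuration for closed-form checks."""
    return SimulationConfig(seed=7, noise_sd_vo2=0.0, noise_sd_hr=0.0)


@pytest.fixture
def random_athlete_factory(quiet_config):
    def make(index: int) -> "AthleteProfile":
        return simulate_athlete(quiet_config, index)
    return make


def constant_power(watts: float, seconds: int, t0: int = 0) -> PowerTimeSeries:
    return PowerTimeSeries(t=np.arange(t0, t0 + seconds),
                           power=np.full(seconds, float(watts)))


@pytest.fixture
def make_power():
    return constant_power
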