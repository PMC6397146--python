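import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diatomseason import SensorSeries, TraitTable, gen_sensor

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def traits() -> TraitTable:
    return TraitTable.bundled()


@pytest.fixture(scope="session")
def sensor_short():
    """Three winter/spring months of 15-minute synthetic sensor data."""
    sensor, truth = gen_sensor("2013-01-01", "2013-04-01", seed=3)
    return sensor, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
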