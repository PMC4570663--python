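import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soilchem3d.synthetic_data import DEFAULT_PHASES, simulate_soil_volume

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_volume():
    """96^3 phase-structured volume shared by alignment/pipeline tests."""
    return simulate_soil_volume((96, 96, 96), DEFAULT_PHASES, 12.0, seed=5)


@pytest.fixture(scope="session")
def tiny_volume():
    """64^3 volume for exhaustive-search comparisons."""
    return simulate_soil_volume((64, 64, 64), DEFAULT_PHASES, 10.0, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
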