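import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ngdmap import AnalysisConfig, synthetic_reporter

settings.register_profile(
    "repro",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reporter():
    """A synthetic stem-loop reporter in the canonical coordinate frame
    (stall 1040, primer 585) on a 1500-nt seeded random backbone."""
    return synthetic_reporter(name="PGK1-SL", seed=1)


@pytest.fixture(scope="session")
def cga_reporter():
    return synthetic_reporter(
        name="PGK1-CGA12", stall_start=950, stall_type="CGA12", seed=2
    )


@pytest.fixture(scope="session")
def control_reporter():
    return synthetic_reporter(
        name="PGK1", stall_start=None, stall_type="none", seed=3
    )


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
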