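import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rmer import RemovalData, RobustDesign, scenario, simulate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def robust10():
    """Robust design with 5 primaries x 2 secondaries (K=10)."""
    return RobustDesign((2,) * 5)


@pytest.fixture
def single10():
    """Single-secondary design with 10 primaries (K=10)."""
    return RobustDesign((1,) * 10)


@pytest.fixture
def const_s2_dataset():
    """One simulated dataset from the on-site-leaning constant scenario."""
    scn = scenario("const-s2", K=20)
    return scn, simulate_scenario(scn, rng=np.random.default_rng(2024))[0]


@pytest.fixture
def toy_data():
    """Tiny two-primary dataset with counts 5,3,2,1."""
    return RemovalData(RobustDesign((2, 2)), np.array([5, 3, 2, 1]))
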