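import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avrescue import synthetic_s1_records

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def s1_table():
    """Synthetic registry-snapshot stand-in shared by the whole suite."""
    return synthetic_s1_records(seed=1)


@pytest.fixture(scope="session")
def depth_dist(s1_table):
    return s1_table.depth_distribution()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
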