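import numpy as np
import pytest
from hypothesis import settings

from boolbayes import GeneratorConfig, generate_study_instance

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_instance():
    """A 6-node time-series instance with known truth."""
    return generate_study_instance(
        GeneratorConfig(n=6, m=80, theta=0.1, seed=5, mode="timeseries")
    )


@pytest.fixture(scope="session")
def tiny_instance():
    """A 3-node instance small enough for exhaustive enumeration."""
    return generate_study_instance(
        GeneratorConfig(n=3, m=40, theta=0.1, seed=7, mode="timeseries")
    )
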