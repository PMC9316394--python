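import numpy as np
import pytest

from symcox import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort from the default (study-condition) mechanism."""
    return generate_cohort(SimulationConfig(n=1500, seed=202))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast smoke tests."""
    return generate_cohort(SimulationConfig(n=250, seed=77))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
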