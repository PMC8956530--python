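import numpy as np
import pytest

from xylosafe.config import StudyConfig
from xylosafe import synthetic


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(n_sites=6, n_trees_per_site=4, seed=123)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A compact but complete synthetic campaign, shared across tests."""
    return synthetic.simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
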