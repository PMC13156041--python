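import numpy as np
import pytest

from ecdg.environments import default_environment_pair
from ecdg.synthetic import simulate_behavior


@pytest.fixture(scope="session")
def openfield_pair():
    return default_environment_pair("openfield")


@pytest.fixture(scope="session")
def corridor_pair():
    return default_environment_pair("corridor")


@pytest.fixture(scope="session")
def short_track(openfield_pair):
    """Small behavior track shared by cheap unit tests (6 runs/context)."""
    return simulate_behavior(openfield_pair, n_runs_per_context=6,
                             block_size=3, seed=123)


@pytest.fixture(scope="session")
def default_track(openfield_pair):
    """Full-size day (15 runs per context in 5-run blocks)."""
    return simulate_behavior(openfield_pair, seed=7)


def rng(seed=0):
    return np.random.default_rng(seed)
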