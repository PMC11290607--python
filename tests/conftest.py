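import numpy as np
import pytest

from facetshift.synthetic import WorldConfig, generate_world, simulate_pure_birth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_world():
    """A 30x30 synthetic landscape shared across read-only tests."""
    return generate_world(WorldConfig(grid_shape=(30, 30), seed=42))


@pytest.fixture(scope="session")
def tree20():
    """A 20-tip pure-birth tree shared across read-only tests."""
    return simulate_pure_birth(20, 1.0, seed=7)
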