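import numpy as np
import pytest

from adrgraph import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-block dataset for fast unit tests."""
    return generate_dataset(SyntheticConfig(
        n_drugs=20, n_side_effects=30, n_blocks=2, p_in=0.6, p_out=0.05,
        n_substructures=24, n_diseases=20, noise_flip=0.02, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The spec-scale fixture (60x120, 3 blocks)."""
    return generate_dataset(SyntheticConfig(seed=1))
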