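import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramanembryo import SimConfig, generate_dataset, preprocess_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size synthetic study at its default configuration."""
    return generate_dataset(SimConfig(seed=2021))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Preprocessed fingerprint matrix of the default study (640 x 1201)."""
    return preprocess_dataset(default_dataset)


@pytest.fixture
def tiny_config():
    """A small but structurally complete simulation for fast I/O tests."""
    return SimConfig(n_blastula=3, n_non_blastula=2, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
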