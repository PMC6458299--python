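import numpy as np
import pytest

from hebbnet.synthetic import ToyDatasetConfig, make_toy_dataset, split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_small():
    """Tiny 3-class toy image set shared across tests (no noise knobs)."""
    cfg = ToyDatasetConfig(n_classes=3, n_per_class=60, noise_sd=0.1, seed=11)
    return make_toy_dataset(cfg)


@pytest.fixture(scope="session")
def toy_split(toy_small):
    return split(toy_small, 0.2, seed=11)
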