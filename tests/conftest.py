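import numpy as np
import pytest

from dermseg.synthetic import SynthConfig, make_dataset, make_sample


@pytest.fixture(scope="session")
def base_config() -> SynthConfig:
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def sample(base_config):
    return make_sample(base_config)


@pytest.fixture(scope="session")
def hairy_samples(base_config):
    """Ten deterministic samples with hairs, shared across tests."""
    return make_dataset(10, base_config)


@pytest.fixture(scope="session")
def hairless_config() -> SynthConfig:
    return SynthConfig(seed=5, n_hairs=0)


@pytest.fixture(scope="session")
def hairless_sample(hairless_config):
    return make_sample(hairless_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
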