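import numpy as np
import pytest

from medcrypt.chaos import ChaosParams
from medcrypt.synthdata import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def key():
    return ChaosParams(initial_state=(0.3, 0.6, 0.7))


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(size=(16, 16), tumour_radius=(2.5, 4.5), seed=0)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_config):
    """120 separable 16x16 phantoms (tumour contrast 80, noise sigma 8)."""
    return generate_dataset(120, 0.5, phantom_config, seed=11)
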