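import numpy as np
import pytest

from feunet.config import NetworkConfig, SyntheticConfig
from feunet.synthetic_data import generate_liver_like


@pytest.fixture(scope="session")
def liver200():
    """200 binary phantoms at 64x64 — the smoke-training study conditions."""
    cfg = SyntheticConfig(task="liver_binary", n_samples=200, size=64, seed=7)
    return generate_liver_like(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_net_config():
    return NetworkConfig(backbone="vgg16", N=3, n=4, n0=3, nc=2)
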