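import numpy as np
import pytest

from odcseg.synth import SynthConfig, generate_scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale generator configuration used across tests."""
    return SynthConfig(image_size=64, n_normal=6, n_glaucoma=4,
                       n_val_glaucoma=4, seed=7)


@pytest.fixture(scope="session")
def tiny_splits(tiny_config):
    return generate_scenario(tiny_config, scenario=1)


@pytest.fixture(scope="session")
def tiny_sample(tiny_splits):
    return tiny_splits["source"][0]
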