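import numpy as np
import pytest

from latentcp import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A small synthetic session shared by read/write and binning tests."""
    cfg = GeneratorConfig(n_neurons=12, n_trials=50, n_frozen=8, seed=42)
    sess, truth = generate_session(cfg)
    return sess, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
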