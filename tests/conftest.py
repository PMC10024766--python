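import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_model():
    """One default-config network shared by the read-only architecture tests."""
    from litesal import ModelConfig, SaliencyNet

    return SaliencyNet(ModelConfig(seed=0))
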