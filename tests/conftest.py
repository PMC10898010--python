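import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest config that still exercises every architectural element."""
    from pestseg import ModelConfig

    return ModelConfig(
        variant="dmsaunet",
        depth=2,
        base_channels=4,
        input_size=(16, 16, 3),
        attention_reduction=4,
    )
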