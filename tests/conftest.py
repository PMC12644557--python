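import numpy as np
import pytest

from seformer.model import ModelConfig


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest valid model: 64x64 input, D=8, one block per level."""
    return ModelConfig(
        input_size=(64, 64), dim=8, conv_channels=(8, 16, 32),
        depths=(1, 1, 1), heads=(2, 4, 8), window=4, se_ratio=4,
        decoder_channels=(16, 8, 8), cross_heads=4, seed=0)


@pytest.fixture(scope="session")
def tiny_batch():
    rng = np.random.default_rng(0)
    x = rng.random((2, 3, 64, 64), dtype=np.float32)
    y = (rng.random((2, 1, 64, 64)) < 0.1).astype(np.float32)
    return x, y
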