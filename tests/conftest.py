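import numpy as np
import pytest

from echoseg.attention import SCBAMConfig
from echoseg.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_cfg():
    """Smallest config that still exercises every structural feature."""
    return ModelConfig(channel_widths=(4, 8, 8, 16), prune_level=2,
                       attention=SCBAMConfig(reduction_ratio=4, spatial_kernel=3))


def zero_mlp_params(c: int, r: int) -> dict:
    hid = max(c // r, 1)
    return {"w1": np.zeros((c, hid)), "b1": np.zeros(hid),
            "w2": np.zeros((hid, c)), "b2": np.zeros(c)}


def zero_conv_params(k: int) -> dict:
    return {"weight": np.zeros((1, 2, k, k)), "bias": np.zeros(1)}
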