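"""Architecture contracts: shapes, determinism, pruning, accounting."""

import numpy as np
import pytest

from echoseg import nn
from echoseg.attention import SCBAMConfig
from echoseg.errors import ConfigurationError, ValidationError
from echoseg.losses import combined_loss
from echoseg.model import (
    ModelConfig, VGGBlock, build, count_flops, count_parameters, prune,
)
from echoseg.nn import Adam, Tensor


def test_forward_shape_contract():
    cfg = ModelConfig(channel_widths=(4, 8), prune_level=1,
                      attention=SCBAMConfig(reduction_ratio=4, spatial_kernel=3))
    m = build(cfg, seed=0)
    outs = m(np.zeros((1, 1, 32, 32), dtype=np.float32))
    assert [o.shape for o in outs] == [(1, 1, 32, 32)]
    probs = outs[0].data
    assert np.all((probs > 0) & (probs < 1)) and np.all(np.isfinite(probs))


def test_indivisible_input_rejected(tiny_model_cfg):
    m = build(tiny_model_cfg, seed=0)
    with pytest.raises(ValidationError):
        m(np.zeros((1, 1, 30, 30), dtype=np.float32))


def test_same_seed_same_weights(tiny_model_cfg):
    a = build(tiny_model_cfg, seed=42)
    b = build(tiny_model_cfg, seed=42)
    for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_eval_forward_deterministic(tiny_model_cfg, rng):
    m = build(tiny_model_cfg, seed=0).eval()
    x = rng.random((2, 1, 16, 16), dtype=np.float32)
    np.testing.assert_array_equal(m.predict(x), m.predict(x))


def test_node_sets_nest_with_prune_level():
    kw = dict(channel_widths=(4, 8, 8, 16, 16),
              attention=SCBAMConfig(reduction_ratio=4, spatial_kernel=3))
    names = {}
    for level in (2, 3):
        m = build(ModelConfig(prune_level=level, **kw), seed=0)
        names[level] = {k for k, _ in m.named_parameters()}
    assert names[2] < names[3]


@pytest.fixture(scope="module")
def parent():
    cfg = ModelConfig(channel_widths=(4, 8, 8, 16, 16), prune_level=4,
                      attention=SCBAMConfig(reduction_ratio=4, spatial_kernel=3))
    return build(cfg, seed=3).eval()


class TestPruning:
    def test_parameter_count_strictly_increases(self, parent):
        counts = [count_parameters(prune(parent, lv)) for lv in (1, 2, 3, 4)]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_prune_to_full_depth_is_identity_count(self, parent):
        assert count_parameters(prune(parent, 4)) == count_parameters(parent)

    def test_pruned_forward_equals_parent_head_exactly(self, parent, rng):
        x = rng.random((2, 1, 32, 32), dtype=np.float32)
        parent_outs = parent(x)
        for lv in (1, 2, 3):
            sub = prune(parent, lv).eval()
            sub_out = sub(x)
            sub_out = sub_out[-1] if isinstance(sub_out, list) else sub_out
            np.testing.assert_array_equal(sub_out.data, parent_outs[lv - 1].data)

    def test_prune_beyond_built_depth_rejected(self, parent):
        with pytest.raises(ValidationError):
            prune(parent, 5)


class TestAccounting:
    def test_single_conv_param_count(self):
        conv = nn.Conv2d(1, 8, 3, rng=np.random.default_rng(0))
        assert sum(p.size for p in conv.parameters()) == 80  # 8*(9+1)

    def test_vgg_block_param_count(self):
        blk = VGGBlock(1, 8, rng=np.random.default_rng(0))
        # 3x3 convs without bias + affine BN: 72 + 16 + 576 + 16
        assert sum(p.size for p in blk.parameters()) == 680

    def test_param_count_independent_of_resolution(self, tiny_model_cfg):
        m = build(tiny_model_cfg, seed=0)
        n0 = count_parameters(m)
        m(np.zeros((1, 1, 16, 16), dtype=np.float32))
        m(np.zeros((1, 1, 32, 32), dtype=np.float32))
        assert count_parameters(m) == n0

    def test_flops_scale_quadratically_with_resolution(self, tiny_model_cfg):
        m = build(tiny_model_cfg, seed=0)
        f1 = count_flops(m, (32, 32))
        f2 = count_flops(m, (64, 64))
        # conv/BN costs all scale with H*W; only the channel MLP does not
        assert abs(f2 / f1 - 4.0) < 0.01

    def test_conv1x1_closed_form(self):
        conv = nn.Conv2d(16, 32, 1, bias=False, rng=np.random.default_rng(0))
        assert conv.flops(7, 7) == 2 * 16 * 32 * 7 * 7


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        ModelConfig(channel_widths=(8,), prune_level=2).validate()
    with pytest.raises(ConfigurationError):
        ModelConfig(channel_widths=(6, 12), prune_level=1,
                    attention=SCBAMConfig(reduction_ratio=4)).validate()
    with pytest.raises(ConfigurationError):
        ModelConfig(attention_mode="simam-only").validate()


def test_config_yaml_round_trip(tmp_path, tiny_model_cfg):
    p = tmp_path / "cfg.yaml"
    tiny_model_cfg.to_yaml(p)
    again = ModelConfig.from_yaml(p)
    assert again == tiny_model_cfg


def test_gradient_flow_overfits_one_pair(rng):
    cfg = ModelConfig(channel_widths=(4, 8), prune_level=1,
                      attention=SCBAMConfig(reduction_ratio=4, spatial_kernel=3))
    m = build(cfg, seed=0)
    x = rng.random((2, 1, 16, 16), dtype=np.float32)
    y = np.zeros((2, 1, 16, 16), dtype=np.float32)
    y[:, :, 4:12, 4:12] = 1.0
    opt = Adam(m.parameters(), lr=1e-3)
    losses = []
    for _ in range(20):
        opt.zero_grad()
        out = m(Tensor(x))[-1]
        loss = combined_loss(out, y)
        losses.append(loss.item())
        loss.backward()
        opt.step()
    assert losses[-1] < losses[0]
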