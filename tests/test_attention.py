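"""Channel/spatial/energy attention operators against hand-derived values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import zero_conv_params, zero_mlp_params
from echoseg.attention import (
    SCBAM, SCBAMConfig, SimAM,
    apply_channel_attention, apply_spatial_attention,
    channel_attention, scbam, simam, spatial_attention,
)
from echoseg.errors import ConfigurationError, ValidationError


def simam_reference(x: np.ndarray, lam: float) -> np.ndarray:
    """Literal per-element evaluation of the energy-based reweighting."""
    c, h, w = x.shape
    out = np.empty_like(x, dtype=np.float64)
    for ch in range(c):
        vals = x[ch].astype(np.float64)
        mu = vals.mean()
        d = (vals - mu) ** 2
        v = d.sum() / (h * w - 1) if h * w > 1 else 0.0
        for i in range(h):
            for j in range(w):
                e_inv = d[i, j] / (4 * (v + lam)) + 0.5
                out[ch, i, j] = vals[i, j] / (1 + np.exp(-e_inv))
    return out


class TestChannelAttention:
    def test_zero_mlp_gives_half_everywhere(self, rng):
        f = rng.random((3, 4, 4))
        mc = channel_attention(f, zero_mlp_params(3, 1), r=1)
        np.testing.assert_allclose(mc, 0.5)
        assert mc.shape == (3, 1, 1)

    def test_identity_mlp_sigmoid_of_avg_plus_max(self):
        # C=1: descriptors avg=3, max=6; identity MLP -> sigmoid(9)
        f = np.array([[[0.0, 2.0], [4.0, 6.0]]])
        params = {"w1": [[1.0]], "b1": [0.0], "w2": [[1.0]], "b2": [0.0]}
        mc = channel_attention(f, params, r=1)
        np.testing.assert_allclose(mc, 1 / (1 + np.exp(-9.0)), rtol=1e-6)

    def test_indivisible_reduction_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            channel_attention(np.zeros((6, 2, 2)), zero_mlp_params(6, 4), r=4)

    def test_nonfinite_input_rejected(self):
        bad = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValidationError):
            channel_attention(bad, zero_mlp_params(2, 1), r=1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equivariant_to_consistent_channel_permutation(self, seed):
        # the bottleneck MLP mixes channels, so permuting the input channels
        # permutes the attention map when the MLP weights are permuted the
        # same way (rows of the first layer, columns/bias of the second)
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((4, 3, 3)).astype(np.float32)
        params = {"w1": rng.standard_normal((4, 2)), "b1": rng.standard_normal(2),
                  "w2": rng.standard_normal((2, 4)), "b2": rng.standard_normal(4)}
        perm = rng.permutation(4)
        permuted = {"w1": params["w1"][perm], "b1": params["b1"],
                    "w2": params["w2"][:, perm], "b2": params["b2"][perm]}
        mc = channel_attention(f, params, r=2)
        mc_perm = channel_attention(f[perm], permuted, r=2)
        np.testing.assert_allclose(mc_perm, mc[perm], rtol=1e-5, atol=1e-7)
        assert np.all(mc > 0) and np.all(mc < 1)

    def test_apply_broadcasts_per_channel(self):
        f = np.full((2, 2, 2), 2.0)
        f[0] *= 2  # channel sums (16, 8) -> scaled by (0.25, 0.5)
        mc = np.array([0.25, 0.5]).reshape(2, 1, 1)
        out = apply_channel_attention(f, mc)
        np.testing.assert_allclose([out[0].sum(), out[1].sum()], [4.0, 4.0])
        with pytest.raises(ValidationError):
            apply_channel_attention(f, np.ones((3, 1, 1)))


class TestSpatialAttention:
    def test_zero_conv_gives_half_everywhere(self, rng):
        f = rng.random((3, 5, 5))
        ms = spatial_attention(f, zero_conv_params(7), k=7)
        assert ms.shape == (1, 5, 5)
        np.testing.assert_allclose(ms, 0.5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            spatial_attention(np.zeros((1, 4, 4)), zero_conv_params(4), k=4)

    def test_delta_kernel_reads_avg_descriptor(self):
        # centred delta on the channel-average descriptor: M_s = sigmoid(F)
        f = np.array([[[0.0, 4.0], [0.0, 0.0]]])
        params = zero_conv_params(3)
        params["weight"][0, 0, 1, 1] = 1.0
        ms = spatial_attention(f, params, k=3)
        np.testing.assert_allclose(
            ms[0], 1 / (1 + np.exp(-f[0])), rtol=1e-6)
        assert abs(ms[0, 0, 1] - 0.98201) < 1e-4

    def test_apply_scales_channels_identically(self, rng):
        f = rng.random((3, 4, 4)) + 0.5
        ms = rng.random((1, 4, 4)) * 0.9 + 0.05
        out = apply_spatial_attention(f, ms)
        ratio = out / f
        np.testing.assert_allclose(ratio[0], ratio[1], rtol=1e-6)
        np.testing.assert_allclose(ratio[2], ms[0], rtol=1e-6)


class TestSimAM:
    def test_constant_channel_zero_variance_limit(self):
        x = np.full((1, 3, 3), 7.0)
        out = simam(x, lam=1e-4)
        np.testing.assert_allclose(out, 7.0 / (1 + np.exp(-0.5)), rtol=1e-6)

    def test_hand_computed_2x2_case(self):
        x = np.array([[[0.0, 0.0], [0.0, 4.0]]])
        out = simam(x, lam=1e-4)
        # mu=1, d={1,1,1,9}, v=4; E_inv(4) = 9/16.0004 + 0.5
        e = 9 / (4 * (4 + 1e-4)) + 0.5
        np.testing.assert_allclose(out[0, 1, 1], 4 / (1 + np.exp(-e)), rtol=1e-6)
        assert abs(out[0, 1, 1] - 2.9724) < 1e-3

    def test_matches_literal_reference(self, rng):
        for _ in range(10):
            x = rng.standard_normal((3, 5, 4)).astype(np.float32)
            ref = simam_reference(x, 1e-4)
            got = simam(x, 1e-4)
            assert np.abs(got - ref).max() / np.abs(ref).max() < 1e-5

    def test_permutation_of_positions_commutes(self, rng):
        x = rng.standard_normal((2, 3, 3)).astype(np.float32)
        flat = x.reshape(2, -1)
        perm = rng.permutation(9)
        out_perm = simam(flat[:, perm].reshape(2, 3, 3), 1e-3).reshape(2, -1)
        out = simam(x, 1e-3).reshape(2, -1)
        np.testing.assert_allclose(out_perm, out[:, perm], rtol=1e-5)

    def test_large_lambda_flattens_attention_monotonically(self, rng):
        x = rng.standard_normal((1, 4, 4)).astype(np.float64)
        flat_gain = 1 / (1 + np.exp(-0.5))
        devs = []
        for lam in (1e-3, 1e-1, 1e1, 1e3):
            gain = simam(x, lam) / x
            devs.append(np.abs(gain - flat_gain).max())
        assert all(a > b for a, b in zip(devs, devs[1:]))

    def test_single_pixel_treated_as_zero_variance(self):
        out = simam(np.array([[[3.0]]]), 1e-4)
        np.testing.assert_allclose(out, 3.0 / (1 + np.exp(-0.5)), rtol=1e-6)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            SimAM(0.0)


class TestSCBAM:
    def test_zero_parameter_composition_constant_input(self):
        cfg = SCBAMConfig(reduction_ratio=1, spatial_kernel=3)
        params = {"mlp": zero_mlp_params(2, 1), "conv": zero_conv_params(3)}
        x = np.full((2, 4, 4), 3.0)
        out = scbam(x, cfg, params)
        expect = 3.0 * 0.5 * (1 / (1 + np.exp(-0.5))) * 0.5
        np.testing.assert_allclose(out, expect, rtol=1e-6)

    @pytest.mark.parametrize("shape", [(4, 6, 6), (2, 4, 8, 8)])
    def test_shape_preserved(self, rng, shape):
        mod = SCBAM(shape[-3], SCBAMConfig(reduction_ratio=2, spatial_kernel=3),
                    rng=np.random.default_rng(0))
        from echoseg.nn import Tensor
        x = rng.standard_normal((1,) + shape if len(shape) == 3 else shape)
        out = mod(Tensor(x.astype(np.float32)))
        assert out.shape == x.shape

    @pytest.mark.parametrize("c,r,k", [(8, 2, 3), (16, 4, 7), (8, 8, 5)])
    def test_learnable_parameter_count(self, c, r, k):
        mod = SCBAM(c, SCBAMConfig(reduction_ratio=r, spatial_kernel=k),
                    rng=np.random.default_rng(0))
        n = sum(p.size for p in mod.parameters())
        assert n == (2 * c * (c // r) + c // r + c) + (2 * k * k + 1)

    def test_deterministic_given_parameters(self, rng):
        from echoseg.nn import Tensor
        mod = SCBAM(4, SCBAMConfig(reduction_ratio=2, spatial_kernel=3),
                    rng=np.random.default_rng(5))
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        a = mod(Tensor(x)).data
        b = mod(Tensor(x)).data
        np.testing.assert_array_equal(a, b)
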