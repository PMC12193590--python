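"""Attention operators: CBAM channel/spatial attention, SimAM, and their fusion.

The fused block ("SCBAM") applies, in order:

1. **Channel attention** — global average- and max-pooled channel descriptors
   pass through one shared two-layer MLP (hidden width C/r); the sigmoid of
   the summed outputs rescales each channel.
2. **SimAM** — a parameter-free energy term: each activation is rescaled by
   ``sigmoid(d_i / (4 (v + lambda)) + 0.5)`` where ``d_i = (x_i - mu)^2`` is
   its squared deviation from the channel mean and ``v`` is the channel
   variance over the H*W positions.
3. **Spatial attention** — channel-wise mean and max maps are concatenated
   and convolved (odd k, zero-padded) to a single sigmoid map that rescales
   every channel by the same spatial pattern.

Module classes operate on autodiff tensors and are what the segmentation
network embeds; the functional wrappers at the bottom take plain numpy
arrays with explicit parameters and exist for direct numerical use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .nn import functional as F
from .nn import Tensor

__all__ = [
    "SCBAMConfig", "ChannelAttention", "SpatialAttention", "SimAM", "SCBAM",
    "channel_attention", "apply_channel_attention",
    "spatial_attention", "apply_spatial_attention",
    "simam", "scbam",
]


@dataclass
class SCBAMConfig:
    """Hyperparameters of the fused attention block.

    reduction_ratio
        Channel-MLP bottleneck ratio r; must divide the channel count.
    spatial_kernel
        Odd kernel size of the spatial-attention convolution.
    simam_lambda
        Positive regulariser added to the channel variance in the energy term.
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    simam_lambda: float = 1e-4

    def validate(self):
        if self.reduction_ratio < 1:
            raise ConfigurationError("reduction_ratio must be a positive integer")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ConfigurationError(
                f"spatial_kernel must be odd, got {self.spatial_kernel}")
        if not self.simam_lambda > 0:
            raise ConfigurationError("simam_lambda must be > 0")
        return self


class ChannelAttention(nn.Module):
    """Shared-MLP channel attention; returns an (N, C, 1, 1) sigmoid map."""

    def __init__(self, channels: int, reduction_ratio: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        if reduction_ratio < 1 or channels % reduction_ratio != 0:
            raise ConfigurationError(
                f"channel count {channels} not divisible by reduction ratio "
                f"{reduction_ratio}")
        hidden = max(channels // reduction_ratio, 1)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def _mlp(self, d):
        return self.fc2(F.relu(self.fc1(d)))

    def forward(self, x: Tensor) -> Tensor:
        n, c, _, _ = x.shape
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        mc = F.sigmoid(self._mlp(avg) + self._mlp(mx))
        return mc.reshape(n, c, 1, 1)

    def flops(self) -> float:
        return 2.0 * (self.fc1.flops() + self.fc2.flops())


class SpatialAttention(nn.Module):
    """Channel-pooled spatial attention; returns an (N, 1, H, W) sigmoid map."""

    def __init__(self, kernel: int = 7, *, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ConfigurationError(f"spatial kernel must be odd, got {kernel}")
        self.conv = nn.Conv2d(2, 1, kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return F.sigmoid(self.conv(F.concat([avg, mx], axis=1)))

    def flops(self, h: int, w: int) -> float:
        return self.conv.flops(h, w)


class SimAM(nn.Module):
    """Parameter-free energy-based attention.

    Each activation is reweighted by ``sigmoid(E_inv)`` with
    ``E_inv = (x - mu)^2 / (4 (v + lambda)) + 0.5``; ``mu`` and ``v`` are the
    per-channel mean and (n-1)-normalised variance over spatial positions.
    A 1x1 spatial extent is the zero-variance degenerate case (v = 0).
    """

    def __init__(self, lam: float = 1e-4):
        super().__init__()
        if not lam > 0:
            raise ConfigurationError("simam lambda must be > 0")
        self.lam = float(lam)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        mu = x.mean(axis=(2, 3), keepdims=True)
        d = (x - mu) ** 2
        denom = max(h * w - 1, 1)
        v = d.sum(axis=(2, 3), keepdims=True) * (1.0 / denom)
        e_inv = d / ((v + np.float32(self.lam)) * 4.0) + np.float32(0.5)
        return x * F.sigmoid(e_inv)


class SCBAM(nn.Module):
    """Fusion block: channel attention, then SimAM, then spatial attention."""

    def __init__(self, channels: int, cfg: SCBAMConfig | None = None, *,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = (cfg or SCBAMConfig()).validate()
        self.channel = ChannelAttention(channels, self.cfg.reduction_ratio, rng=rng)
        self.simam = SimAM(self.cfg.simam_lambda)
        self.spatial = SpatialAttention(self.cfg.spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel(x)
        x = self.simam(x)
        return x * self.spatial(x)

    def flops(self, h: int, w: int) -> float:
        return self.channel.flops() + self.spatial.flops(h, w)


# ---------------------------------------------------------------------------
# Functional API on plain numpy arrays with explicit parameters.
# ---------------------------------------------------------------------------

def _as_batched(f) -> tuple[np.ndarray, bool]:
    arr = np.asarray(f, dtype=np.float32)
    if arr.ndim == 3:
        return arr[None], False
    if arr.ndim == 4:
        return arr, True
    raise ValidationError(f"expected a (C,H,W) or (N,C,H,W) array, got shape {arr.shape}")


def _check_finite(arr: np.ndarray):
    if not np.all(np.isfinite(arr)):
        raise ValidationError("feature map contains non-finite values")


def channel_attention(f, mlp_params: dict, r: int) -> np.ndarray:
    """Channel attention map from explicit shared-MLP parameters.

    ``mlp_params`` holds ``w1`` (C, C/r), ``b1`` (C/r,), ``w2`` (C/r, C),
    ``b2`` (C,).  Returns a map shaped (C, 1, 1) (batched input keeps its
    leading axis) with entries strictly inside (0, 1).
    """
    x, batched = _as_batched(f)
    _check_finite(x)
    c = x.shape[1]
    mod = ChannelAttention(c, r, rng=np.random.default_rng(0))
    mod.load_state_dict({
        "fc1.weight": np.asarray(mlp_params["w1"], dtype=np.float32),
        "fc1.bias": np.asarray(mlp_params["b1"], dtype=np.float32),
        "fc2.weight": np.asarray(mlp_params["w2"], dtype=np.float32),
        "fc2.bias": np.asarray(mlp_params["b2"], dtype=np.float32),
    })
    out = mod(Tensor(x)).data
    return out if batched else out[0]


def apply_channel_attention(f, m_c) -> np.ndarray:
    """Rescale channels: F' = M_c * F with (C,1,1) broadcasting."""
    x, batched = _as_batched(f)
    m, mb = _as_batched(m_c)
    if m.shape[1] != x.shape[1] or m.shape[2:] != (1, 1):
        raise ValidationError(
            f"channel map shape {np.shape(m_c)} does not broadcast over {np.shape(f)}")
    out = x * m
    return out if batched else out[0]


def spatial_attention(f, conv_params: dict, k: int) -> np.ndarray:
    """Spatial attention map from explicit conv parameters.

    ``conv_params`` holds ``weight`` (1, 2, k, k) and ``bias`` (1,).  Returns
    a map shaped (1, H, W) (batched: (N, 1, H, W)).
    """
    x, batched = _as_batched(f)
    _check_finite(x)
    mod = SpatialAttention(k, rng=np.random.default_rng(0))
    mod.load_state_dict({
        "conv.weight": np.asarray(conv_params["weight"], dtype=np.float32),
        "conv.bias": np.asarray(conv_params["bias"], dtype=np.float32),
    })
    out = mod(Tensor(x)).data
    return out if batched else out[0]


def apply_spatial_attention(f, m_s) -> np.ndarray:
    """Rescale positions: F'' = M_s * F' with (1,H,W) broadcasting."""
    x, batched = _as_batched(f)
    m, _ = _as_batched(m_s)
    if m.shape[1] != 1 or m.shape[2:] != x.shape[2:]:
        raise ValidationError(
            f"spatial map shape {np.shape(m_s)} does not broadcast over {np.shape(f)}")
    out = x * m
    return out if batched else out[0]


def simam(f, lam: float = 1e-4) -> np.ndarray:
    """SimAM reweighting of a feature map (no learnable parameters)."""
    x, batched = _as_batched(f)
    _check_finite(x)
    out = SimAM(lam)(Tensor(x)).data
    return out if batched else out[0]


def scbam(f, cfg: SCBAMConfig, params: dict) -> np.ndarray:
    """Full fused block from explicit parameters.

    ``params`` holds ``mlp`` (see :func:`channel_attention`) and ``conv``
    (see :func:`spatial_attention`).
    """
    cfg.validate()
    x, batched = _as_batched(f)
    mc = channel_attention(x, params["mlp"], cfg.reduction_ratio)
    x1 = apply_channel_attention(x, mc)
    x2 = simam(x1, cfg.simam_lambda)
    ms = spatial_attention(x2, params["conv"], cfg.spatial_kernel)
    out = apply_spatial_attention(x2, ms)
    return out if batched else out[0]
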