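"""Pruned nested UNet (UNet++) with fused attention for LV segmentation.

The network is the UNet++ dense node grid X^{i,j} (depth i, skip column j)
truncated at a prune level L:

* the backbone column X^{i,0} extracts features at resolution H/2^i; rows
  i >= 1 can use a *nested* block that dips one further resolution level
  (1x1 skip conv, max-pool, VGG conv pair, transposed-conv upsample, concat,
  second VGG conv pair, attention) instead of a plain VGG block;
* every decoder node X^{i,j} (j >= 1) fuses all same-row predecessors with a
  transposed-conv upsample of X^{i+1,j-1}, then applies a VGG conv pair and
  the fused attention block;
* deep supervision attaches a 1x1 sigmoid head to every top-row node
  X^{0,j}, so each sub-network L1..L4 can predict on its own and the graph
  can be pruned to any level at test time while sharing weights.

VGG conv pairs are 3x3 convolutions (no bias) each followed by batch
normalisation and ReLU; spatial size is always preserved inside a node.

FLOP accounting uses a pinned convention: one multiply-accumulate of a
convolution, transposed convolution or linear layer counts as 2 FLOPs, a
batch-norm output element as 2 FLOPs; pooling, activations and attention
rescalings are not counted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .attention import SCBAM, SCBAMConfig
from .errors import ConfigurationError, ValidationError
from .nn import functional as F
from .nn import Tensor

__all__ = [
    "ModelConfig", "VGGBlock", "NestedUNetBlock", "DAUNetPP",
    "build", "prune", "count_parameters", "count_flops",
]


@dataclass
class ModelConfig:
    """Structural description of one network instance."""

    in_channels: int = 1
    channel_widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    prune_level: int = 3
    deep_supervision: bool = True
    attention: SCBAMConfig = field(default_factory=SCBAMConfig)
    attention_mode: str = "scbam"      # "scbam" | "none"
    nested_encoder: bool = True        # nested blocks on backbone rows i >= 1
    nested_mid_factor: int = 1         # width multiplier inside nested blocks

    def validate(self) -> "ModelConfig":
        if self.prune_level not in (1, 2, 3, 4):
            raise ConfigurationError(f"prune_level must be 1..4, got {self.prune_level}")
        if len(self.channel_widths) < self.prune_level + 1:
            raise ConfigurationError(
                f"need {self.prune_level + 1} channel widths, got {len(self.channel_widths)}")
        if self.attention_mode not in ("scbam", "none"):
            raise ConfigurationError(f"unknown attention_mode {self.attention_mode!r}")
        if self.attention_mode == "scbam":
            self.attention.validate()
            r = self.attention.reduction_ratio
            for w in self.channel_widths[: self.prune_level + 1]:
                if w % r != 0:
                    raise ConfigurationError(
                        f"channel width {w} not divisible by reduction ratio {r}")
        return self

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_widths"] = list(self.channel_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = SCBAMConfig(**d["attention"])
        if "channel_widths" in d:
            d["channel_widths"] = tuple(d["channel_widths"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("model", doc))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.to_dict()}, fh, sort_keys=False)


class VGGBlock(nn.Module):
    """Two 3x3 conv + BN + ReLU stages, optional attention at the end."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 attention: SCBAMConfig | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.att = SCBAM(out_ch, attention, rng=rng) if attention else None

    def forward(self, x):
        x = F.relu(self.bn1(self.conv1(x)))
        x = F.relu(self.bn2(self.conv2(x)))
        return self.att(x) if self.att is not None else x

    def flops(self, h: int, w: int) -> float:
        f = (self.conv1.flops(h, w) + self.bn1.flops(h, w)
             + self.conv2.flops(h, w) + self.bn2.flops(h, w))
        if self.att is not None:
            f += self.att.flops(h, w)
        return f


class NestedUNetBlock(nn.Module):
    """Deeper feature-extraction block operating at a fixed resolution.

    A 1x1 convolution preserves the incoming information on a skip path;
    the main path max-pools to half resolution, runs a VGG conv pair,
    upsamples back with a 2x2 transposed convolution, concatenates with the
    skip, runs a second VGG conv pair and finally the attention block.
    """

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 attention: SCBAMConfig | None = None, mid_factor: int = 1):
        super().__init__()
        mid = out_ch * mid_factor
        self.skip = nn.Conv2d(in_ch, out_ch, 1, rng=rng)
        self.vgg1 = VGGBlock(in_ch, mid, rng=rng)
        self.up = nn.ConvTranspose2d(mid, out_ch, rng=rng)
        self.vgg2 = VGGBlock(2 * out_ch, out_ch, rng=rng)
        self.att = SCBAM(out_ch, attention, rng=rng) if attention else None

    def forward(self, x):
        s = self.skip(x)
        y = self.vgg1(F.maxpool2x2(x))
        y = self.up(y)
        y = self.vgg2(F.concat([s, y], axis=1))
        return self.att(y) if self.att is not None else y

    def flops(self, h: int, w: int) -> float:
        hh, ww = h // 2, w // 2
        f = (self.skip.flops(h, w) + self.vgg1.flops(hh, ww)
             + self.up.flops(hh, ww) + self.vgg2.flops(h, w))
        if self.att is not None:
            f += self.att.flops(h, w)
        return f


class DAUNetPP(nn.Module):
    """The pruned, attention-augmented nested UNet."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        L = cfg.prune_level
        w = list(cfg.channel_widths[: L + 1])
        att = cfg.attention if cfg.attention_mode == "scbam" else None

        # backbone column j = 0
        self._set_node(0, 0, VGGBlock(cfg.in_channels, w[0], rng=rng, attention=att))
        for i in range(1, L + 1):
            if cfg.nested_encoder:
                blk = NestedUNetBlock(w[i - 1], w[i], rng=rng, attention=att,
                                      mid_factor=cfg.nested_mid_factor)
            else:
                blk = VGGBlock(w[i - 1], w[i], rng=rng, attention=att)
            self._set_node(i, 0, blk)

        # decoder grid j >= 1
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                setattr(self, f"up_{i}_{j}", nn.ConvTranspose2d(w[i + 1], w[i], rng=rng))
                self._set_node(i, j, VGGBlock((j + 1) * w[i], w[i], rng=rng, attention=att))

        for j in range(1, L + 1):
            setattr(self, f"head_{j}", nn.Conv2d(w[0], 1, 1, rng=rng))

    def _set_node(self, i, j, block):
        setattr(self, f"node_{i}_{j}", block)

    def _node(self, i, j):
        return getattr(self, f"node_{i}_{j}")

    def _required_divisor(self) -> int:
        extra = 1 if self.cfg.nested_encoder else 0
        return 2 ** (self.cfg.prune_level + extra)

    def forward(self, x):
        """Map (N, C_in, H, W) images to per-level probability masks.

        Returns a list of (N, 1, H, W) sigmoid outputs, one per sub-network
        column, when deep supervision is on; otherwise the deepest output.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValidationError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}")
        div = self._required_divisor()
        _, _, h, w = x.shape
        if h % div or w % div:
            raise ValidationError(
                f"input {h}x{w} not divisible by {div} "
                f"(prune level {self.cfg.prune_level})")
        L = self.cfg.prune_level
        X: dict[tuple[int, int], Tensor] = {}
        X[0, 0] = self._node(0, 0)(x)
        for i in range(1, L + 1):
            X[i, 0] = self._node(i, 0)(F.maxpool2x2(X[i - 1, 0]))
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                up = getattr(self, f"up_{i}_{j}")(X[i + 1, j - 1])
                inputs = [X[i, jj] for jj in range(j)] + [up]
                X[i, j] = self._node(i, j)(F.concat(inputs, axis=1))
        outs = [F.sigmoid(getattr(self, f"head_{j}")(X[0, j])) for j in range(1, L + 1)]
        if not np.all(np.isfinite(outs[-1].data)):
            raise RuntimeError("non-finite activations in forward pass")
        return outs if self.cfg.deep_supervision else outs[-1]

    def predict(self, x) -> np.ndarray:
        """Deepest-head probability masks as a numpy array (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(x)
        finally:
            self.train(was_training)
        out = out[-1] if isinstance(out, list) else out
        return out.data

    def count_flops(self, input_hw: tuple[int, int]) -> float:
        """Forward FLOPs for one sample under the pinned convention."""
        h, w = input_hw
        div = self._required_divisor()
        if h % div or w % div:
            raise ValidationError(f"input {h}x{w} not divisible by {div}")
        L = self.cfg.prune_level
        total = 0.0
        for i in range(0, L + 1):
            hi, wi = h >> i, w >> i
            total += self._node(i, 0).flops(hi, wi)
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                hi, wi = h >> i, w >> i
                total += getattr(self, f"up_{i}_{j}").flops(hi >> 1, wi >> 1)
                total += self._node(i, j).flops(hi, wi)
        for j in range(1, L + 1):
            total += getattr(self, f"head_{j}").flops(h, w)
        return total


def build(cfg: ModelConfig, seed: int = 0) -> DAUNetPP:
    """Construct a network with seeded (reproducible) initial weights."""
    return DAUNetPP(cfg, rng=np.random.default_rng(seed))


def prune(model: DAUNetPP, level: int) -> DAUNetPP:
    """Extract the sub-network that feeds the level-``level`` output head.

    The returned model *shares* parameter and batch-norm buffer storage with
    the parent, so its forward pass reproduces the parent's deep-supervision
    output at that level exactly (in eval mode).
    """
    if level > model.cfg.prune_level:
        raise ValidationError(
            f"cannot prune to level {level}: model was built at "
            f"level {model.cfg.prune_level}")
    sub_cfg = dataclasses.replace(model.cfg, prune_level=level)
    sub = DAUNetPP(sub_cfg, rng=np.random.default_rng(0))
    parent_params = dict(model.named_parameters())
    parent_bufs = dict(model.named_buffers())

    def owner_of(root: nn.Module, dotted: str):
        parts = dotted.split(".")
        mod = root
        for p in parts[:-1]:
            mod = mod._modules[p]
        return mod, parts[-1]

    for name, _ in list(sub.named_parameters()):
        mod, leaf = owner_of(sub, name)
        setattr(mod, leaf, parent_params[name])
    for name, _ in list(sub.named_buffers()):
        mod, leaf = owner_of(sub, name)
        mod.register_buffer(leaf, parent_bufs[name])
    return sub


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars."""
    return int(sum(p.size for p in model.parameters()))


def count_flops(model: DAUNetPP, input_shape) -> float:
    """Forward FLOPs for ``input_shape`` = (H, W) or (N, C, H, W)."""
    if len(input_shape) == 4:
        h, w = input_shape[2], input_shape[3]
    elif len(input_shape) == 2:
        h, w = input_shape
    else:
        raise ValidationError(f"bad input_shape {input_shape}")
    return model.count_flops((h, w))
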