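"""Segmentation losses and overlap metrics.

Training optimises ``alpha * DiceLoss + (1 - alpha) * BCELoss`` on raw
sigmoid probabilities (soft Dice); evaluation uses hard Dice/IoU after
binarising the prediction at 0.5.  Both overlap ratios carry an additive
smoothing epsilon so that two empty masks score 1 rather than 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "LossConfig", "dice_coefficient", "iou", "dice_loss", "bce_loss",
    "combined_loss", "evaluate_with_ci",
]

SMOOTH_EPS = 1e-6
CLIP_EPS = 1e-6


@dataclass
class LossConfig:
    """alpha weights Dice loss against BCE loss (alpha=1 -> pure Dice)."""

    alpha: float = 0.8
    smooth_eps: float = SMOOTH_EPS

    def validate(self) -> "LossConfig":
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0,1], got {self.alpha}")
        if not self.smooth_eps > 0:
            raise ValidationError("smooth_eps must be > 0")
        return self


def _np(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)


def _check_pair(pred: np.ndarray, target: np.ndarray):
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    tvals = np.unique(target)
    if not np.all(np.isin(tvals, (0.0, 1.0))):
        raise ValidationError("ground-truth mask must be binary (0/1)")
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValidationError("prediction must hold probabilities in [0,1]")


def dice_coefficient(pred, target, *, threshold: float = 0.5,
                     eps: float = SMOOTH_EPS) -> float:
    """Hard Dice 2|A∩B| / (|A|+|B|) after binarising ``pred``."""
    p, g = _np(pred), _np(target).astype(np.float32)
    _check_pair(p, g)
    a = (p >= threshold).astype(np.float64)
    inter = float((a * g).sum())
    return (2.0 * inter + eps) / (a.sum() + g.sum() + eps)


def iou(pred, target, *, threshold: float = 0.5, eps: float = SMOOTH_EPS) -> float:
    """Hard intersection-over-union |A∩B| / |A∪B|."""
    p, g = _np(pred), _np(target).astype(np.float32)
    _check_pair(p, g)
    a = (p >= threshold).astype(np.float64)
    inter = float((a * g).sum())
    union = a.sum() + g.sum() - inter
    return (inter + eps) / (union + eps)


def dice_loss(pred, target, *, eps: float = SMOOTH_EPS):
    """Soft Dice loss 1 - 2 Σ p·g / (Σ p + Σ g) on raw probabilities.

    Returns an autodiff scalar when ``pred`` is a graph tensor, else a float.
    """
    if isinstance(pred, Tensor):
        g = Tensor(_np(target))
        num = (pred * g).sum() * 2.0 + np.float32(eps)
        den = pred.sum() + g.sum() + np.float32(eps)
        return Tensor(np.float32(1.0)) - num / den
    p, g = _np(pred), _np(target).astype(np.float32)
    _check_pair(p, g)
    return 1.0 - (2.0 * float((p * g).sum()) + eps) / (float(p.sum() + g.sum()) + eps)


def bce_loss(pred, target, *, eps: float = CLIP_EPS):
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    if isinstance(pred, Tensor):
        g = Tensor(_np(target))
        p = F.clip(pred, eps, 1.0 - eps)
        ll = g * F.log(p) + (Tensor(np.float32(1.0)) - g) * F.log(Tensor(np.float32(1.0)) - p)
        return -ll.mean()
    p, g = _np(pred), _np(target).astype(np.float64)
    _check_pair(p.astype(np.float32), g.astype(np.float32))
    p = np.clip(p.astype(np.float64), eps, 1.0 - eps)
    return float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())


def combined_loss(pred, target, cfg: LossConfig | None = None):
    """alpha-weighted sum of soft Dice loss and BCE loss."""
    cfg = (cfg or LossConfig()).validate()
    d = dice_loss(pred, target, eps=cfg.smooth_eps)
    b = bce_loss(pred, target)
    if isinstance(pred, Tensor):
        return d * np.float32(cfg.alpha) + b * np.float32(1.0 - cfg.alpha)
    return cfg.alpha * d + (1.0 - cfg.alpha) * b


def evaluate_with_ci(pairs, n_boot: int = 1000, seed: int = 0,
                     *, threshold: float = 0.5) -> dict:
    """Mean Dice/IoU over (pred, target) pairs with percentile bootstrap CIs.

    Frames are the resampling unit; the CI is the [2.5%, 97.5%] percentile
    interval of the bootstrap distribution of the per-frame mean.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 mask pairs for a CI")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    dsc = np.array([dice_coefficient(p, g, threshold=threshold) for p, g in pairs])
    jac = np.array([iou(p, g, threshold=threshold) for p, g in pairs])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=(n_boot, len(pairs)))
    dsc_boot = dsc[idx].mean(axis=1)
    jac_boot = jac[idx].mean(axis=1)
    return {
        "n": len(pairs),
        "dsc_mean": float(dsc.mean()),
        "dsc_ci": (float(np.percentile(dsc_boot, 2.5)),
                   float(np.percentile(dsc_boot, 97.5))),
        "iou_mean": float(jac.mean()),
        "iou_ci": (float(np.percentile(jac_boot, 2.5)),
                   float(np.percentile(jac_boot, 97.5))),
        "dsc_per_frame": dsc,
        "iou_per_frame": jac,
    }
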