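"""Training and evaluation orchestration.

The training recipe follows the reference protocol: Adam at learning rate
1e-4, batch size 2, the alpha-weighted Dice+BCE loss (alpha = 0.8) averaged
over all deep-supervision heads, with the best-validation-Dice checkpoint
retained.  Everything is seeded — weight init, batch order — so a run is
reproducible on CPU bit for bit, and every run writes a manifest that
records the configuration, seed, per-epoch history and an environment
fingerprint.

Checkpoints are ``.npz`` archives whose keys are the dotted parameter and
buffer names of :meth:`echoseg.nn.Module.state_dict` plus a ``__config__``
JSON string holding the model configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ef_from_masks, ef_from_video
from .errors import ConfigurationError, ValidationError
from .losses import LossConfig, combined_loss, dice_coefficient, evaluate_with_ci, iou
from .model import DAUNetPP, ModelConfig, build
from .nn import Adam, Tensor
from .synth import EchoSequence

log = logging.getLogger("echoseg")

__all__ = [
    "TrainConfig", "RunManifest", "train", "evaluate_sequences",
    "save_checkpoint", "load_checkpoint", "sequences_to_arrays",
    "split_sequences", "run_ablation",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 50
    alpha: float = 0.8
    prune_level: int = 3
    seed: int = 0
    device: str = "cpu"

    def validate(self) -> "TrainConfig":
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("hyperparameters must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0,1], got {self.alpha}")
        if self.device != "cpu":
            raise ConfigurationError("only CPU execution is supported")
        return self


@dataclass
class RunManifest:
    train_config: dict
    model_config: dict
    seed: int
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = float("nan")
    environment: dict = field(default_factory=dict)

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @staticmethod
    def fingerprint() -> dict:
        return {"python": platform.python_version(),
                "numpy": np.__version__,
                "machine": platform.machine()}


def sequences_to_arrays(sequences) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into (N,1,H,W) frame and mask arrays."""
    frames = np.concatenate([s.frames for s in sequences])[:, None]
    masks = np.concatenate([s.masks for s in sequences])[:, None].astype(np.float32)
    return frames.astype(np.float32), masks


def split_sequences(sequences, filelist: pd.DataFrame) -> dict[str, list[EchoSequence]]:
    """Group sequences by the manifest's Split column (TRAIN/VAL/TEST)."""
    if len(sequences) != len(filelist):
        raise ValidationError("manifest length does not match sequence count")
    out: dict[str, list[EchoSequence]] = {}
    for seq, split in zip(sequences, filelist["Split"]):
        out.setdefault(str(split), []).append(seq)
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DAUNetPP, path):
    state = {k: np.asarray(v) for k, v in model.state_dict().items()}
    np.savez(path, __config__=json.dumps(model.cfg.to_dict()), **state)


def load_checkpoint(path) -> DAUNetPP:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = build(cfg, seed=0)
    model.load_state_dict(state)
    return model.eval()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_val_dsc(model: DAUNetPP, frames: np.ndarray, masks: np.ndarray,
                   batch: int = 4) -> tuple[float, float]:
    ds, js = [], []
    for lo in range(0, len(frames), batch):
        probs = model.predict(frames[lo:lo + batch])
        for p, g in zip(probs, masks[lo:lo + batch]):
            ds.append(dice_coefficient(p, g))
            js.append(iou(p, g))
    return float(np.mean(ds)), float(np.mean(js))


def train(train_cfg: TrainConfig, model_cfg: ModelConfig,
          train_seqs, val_seqs, *, out_dir=None,
          progress: bool = False) -> tuple[DAUNetPP, RunManifest]:
    """Fit the network on (frame, mask) pairs drawn from the sequences.

    Returns the model restored to its best-validation-Dice weights plus the
    run manifest.  ``out_dir`` (optional) receives ``checkpoint.npz`` and
    ``manifest.json``.
    """
    train_cfg.validate()
    model_cfg = dataclasses.replace(model_cfg, prune_level=train_cfg.prune_level)
    model = build(model_cfg, seed=train_cfg.seed)
    loss_cfg = LossConfig(alpha=train_cfg.alpha)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)

    xtr, ytr = sequences_to_arrays(train_seqs)
    xval, yval = sequences_to_arrays(val_seqs)

    manifest = RunManifest(train_config=dataclasses.asdict(train_cfg),
                           model_config=model_cfg.to_dict(),
                           seed=train_cfg.seed,
                           environment=RunManifest.fingerprint())
    best = {"dsc": -1.0, "state": None, "epoch": -1}
    n = len(xtr)
    for epoch in range(train_cfg.epochs):
        t0 = time.time()
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            opt.zero_grad()
            outs = model(Tensor(xtr[idx]))
            outs = outs if isinstance(outs, list) else [outs]
            loss = None
            for o in outs:
                term = combined_loss(o, ytr[idx], loss_cfg)
                loss = term if loss is None else loss + term
            loss = loss * np.float32(1.0 / len(outs))
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {lo // train_cfg.batch_size}")
            loss.backward()
            opt.step()
            losses.append(lval)
        val_dsc, val_iou = _epoch_val_dsc(model, xval, yval)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_dsc": val_dsc, "val_iou": val_iou,
               "seconds": round(time.time() - t0, 2)}
        manifest.history.append(row)
        if progress:
            log.info("epoch %d: loss=%.4f val_dsc=%.4f val_iou=%.4f (%.1fs)",
                     epoch, row["train_loss"], val_dsc, val_iou, row["seconds"])
        if val_dsc > best["dsc"]:
            best = {"dsc": val_dsc, "epoch": epoch,
                    "state": {k: v.copy() for k, v in model.state_dict().items()}}

    if best["state"] is not None:
        model.load_state_dict(best["state"])
    manifest.best_epoch = best["epoch"]
    manifest.best_val_dsc = best["dsc"]
    model.eval()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out / "checkpoint.npz")
        manifest.to_json(out / "manifest.json")
    return model, manifest


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_sequences(model: DAUNetPP, sequences, *, ids=None,
                       n_boot: int = 1000, seed: int = 0,
                       threshold: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Per-frame Dice/IoU (with ED/ES phase labels) and bootstrap summary.

    Returns ``(per_frame, summary)``; ``per_frame`` has columns
    frame_id, sequence_id, phase (ED/ES/MID), dsc, iou.
    """
    ids = ids or [f"seq{i:04d}" for i in range(len(sequences))]
    rows, pairs = [], []
    for sid, seq in zip(ids, sequences):
        probs = []
        for lo in range(0, seq.n_frames, 4):
            probs.append(model.predict(seq.frames[lo:lo + 4, None]))
        probs = np.concatenate(probs)[:, 0]
        for k in range(seq.n_frames):
            phase = "ED" if k == seq.ed_index else ("ES" if k == seq.es_index else "MID")
            d = dice_coefficient(probs[k], seq.masks[k], threshold=threshold)
            j = iou(probs[k], seq.masks[k], threshold=threshold)
            rows.append({"frame_id": f"{sid}/{k:03d}", "sequence_id": sid,
                         "phase": phase, "dsc": d, "iou": j})
            pairs.append((probs[k], seq.masks[k]))
    per_frame = pd.DataFrame(rows)
    summary = evaluate_with_ci(pairs, n_boot=n_boot, seed=seed, threshold=threshold)
    summary.pop("dsc_per_frame")
    summary.pop("iou_per_frame")
    for phase in ("ED", "ES"):
        sel = per_frame[per_frame["phase"] == phase]
        if len(sel):
            summary[f"dsc_{phase.lower()}"] = float(sel["dsc"].mean())
            summary[f"iou_{phase.lower()}"] = float(sel["iou"].mean())
    return per_frame, summary


def run_ablation(train_cfg: TrainConfig, model_cfg: ModelConfig,
                 train_seqs, val_seqs, test_seqs, *,
                 attention_modes=("none", "scbam"),
                 prune_levels=(1, 2, 3)) -> pd.DataFrame:
    """Re-train across attention {none, fused} x prune levels; tabulate Dice/IoU.

    A structural miniature of an ablation study: one row per variant with
    mean test Dice/IoU, parameter count and epoch count.
    """
    from .model import count_parameters
    rows = []
    for mode in attention_modes:
        for level in prune_levels:
            mcfg = dataclasses.replace(model_cfg, attention_mode=mode)
            tcfg = dataclasses.replace(train_cfg, prune_level=level)
            mdl, man = train(tcfg, mcfg, train_seqs, val_seqs)
            _, summary = evaluate_sequences(mdl, test_seqs, n_boot=200,
                                            seed=tcfg.seed)
            rows.append({"attention": mode, "prune_level": level,
                         "params": count_parameters(mdl),
                         "dsc": summary["dsc_mean"], "iou": summary["iou_mean"]})
    return pd.DataFrame(rows)


def ef_reports(model: DAUNetPP, sequences, *, ids=None,
               use_ground_truth: bool = False):
    """EF report per sequence, from predictions or ground-truth masks."""
    ids = ids or [f"seq{i:04d}" for i in range(len(sequences))]
    reports = []
    for sid, seq in zip(ids, sequences):
        if use_ground_truth:
            reports.append(ef_from_masks(seq.masks, sequence_id=sid))
        else:
            reports.append(ef_from_video(model, seq.frames, sequence_id=sid))
    return reports
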