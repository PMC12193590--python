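"""Synthetic echocardiogram generator.

Emulates the geometry and noise statistics of an apical four-chamber
ultrasound view well enough to exercise segmentation and ejection-fraction
code without any real data: a sector-shaped field of view, a dark elliptical
left-ventricular blood pool inside a bright myocardial rim over mid-grey
tissue, multiplicative Rayleigh speckle (normalised to unit mean) and a
Gaussian point-spread blur.  The pool area follows one smooth cardiac cycle

    area(t) = ES_area + (ED_area - ES_area) * (1 + cos(2*pi*t/T)) / 2

so frame 0 is end-diastole and frame T/2 end-systole, and the ejection
fraction implied by the generated masks is known by construction.  Masks are
the noise-free ellipse interiors.  Everything is reproducible bit for bit
from the configured seed.

The manifest written by :func:`make_dataset` mirrors the EchoNet-Dynamic CSV
dialect (``FileList.csv`` with FileName/EF/Split, EF in percent, and
``VolumeTracings.csv`` with X1,Y1,X2,Y2,Frame rows giving consecutive
contour segments of the ED and ES masks; X is the column coordinate,
0-based frames).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .errors import ValidationError

__all__ = [
    "SynthConfig", "EchoSequence", "make_sequence", "make_dataset",
    "write_sequence", "read_sequence", "write_dataset",
]


@dataclass
class SynthConfig:
    """Parameters of one synthetic cardiac-cycle clip."""

    image_size: int = 112
    n_frames: int = 20
    ef_target: float = 0.60
    ed_area_px: float | None = None     # default: 10% of the frame area
    sector_angle_deg: float = 75.0
    sector_radius_frac: float = 0.95
    lv_center: tuple[float, float] = (0.52, 0.50)   # (row, col) fractions
    lv_aspect: float = 1.7              # long-axis / short-axis ratio
    lv_tilt_deg: float = 0.0
    myo_thickness: float = 0.30         # rim width relative to semi-axes
    speckle_scale: float = 0.5          # 0 = no speckle, 1 = full Rayleigh
    blur_sigma: float = 1.0
    pool_intensity: float = 0.12
    myo_intensity: float = 0.85
    tissue_intensity: float = 0.45
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if not 0.0 < self.ef_target < 1.0:
            raise ValidationError(f"ef_target must lie in (0,1), got {self.ef_target}")
        if self.image_size < 16:
            raise ValidationError("image_size too small")
        if self.n_frames < 2:
            raise ValidationError("need at least 2 frames per cycle")
        area = self.resolved_ed_area()
        if area * (1.0 - self.ef_target) < 16:
            raise ValidationError("end-systolic pool would be unresolvable "
                                  f"({area * (1 - self.ef_target):.0f} px)")
        if not 0.0 <= self.speckle_scale <= 1.0:
            raise ValidationError("speckle_scale must lie in [0,1]")
        return self

    def resolved_ed_area(self) -> float:
        return float(self.ed_area_px if self.ed_area_px is not None
                     else 0.10 * self.image_size ** 2)


@dataclass
class EchoSequence:
    """One synthetic clip: frames, paired masks and the ground-truth EF."""

    frames: np.ndarray          # (T, H, W) float32 in [0,1]
    masks: np.ndarray           # (T, H, W) uint8 in {0,1}
    ed_index: int
    es_index: int
    true_ef: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _sector_mask(size: int, cfg: SynthConfig) -> np.ndarray:
    apex = (2.0, size / 2.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - apex[0], xx - apex[1]
    r = np.hypot(dy, dx)
    ang = np.degrees(np.arctan2(dx, dy))    # angle from straight-down axis
    half = cfg.sector_angle_deg / 2.0
    return (np.abs(ang) <= half) & (r <= cfg.sector_radius_frac * (size - apex[0]))


def _ellipse_mask(size: int, center, a: float, b: float, tilt_deg: float) -> np.ndarray:
    """Interior of an ellipse with semi-axes a (cols) and b (rows)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy, cx = center
    th = np.radians(tilt_deg)
    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_sequence(cfg: SynthConfig) -> EchoSequence:
    """Generate one cardiac cycle from the configuration (deterministic)."""
    cfg.validate()
    size = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    ed_area = cfg.resolved_ed_area()
    es_area = ed_area * (1.0 - cfg.ef_target)
    t = np.arange(cfg.n_frames)
    areas = es_area + (ed_area - es_area) * (1 + np.cos(2 * np.pi * t / cfg.n_frames)) / 2

    a0 = np.sqrt(ed_area / (np.pi * cfg.lv_aspect))   # ED short semi-axis
    b0 = cfg.lv_aspect * a0                           # ED long semi-axis
    center = (cfg.lv_center[0] * size, cfg.lv_center[1] * size)
    sector = _sector_mask(size, cfg)

    ed_ellipse = _ellipse_mask(size, center, a0, b0, cfg.lv_tilt_deg)
    rim_scale = 1.0 + cfg.myo_thickness
    ed_rim = _ellipse_mask(size, center, rim_scale * a0, rim_scale * b0, cfg.lv_tilt_deg)
    if np.any(ed_rim & ~sector):
        raise ValidationError("LV ellipse (with myocardial rim) exceeds the "
                              "sector field of view; shrink ed_area_px or "
                              "recentre lv_center")

    frames = np.empty((cfg.n_frames, size, size), dtype=np.float32)
    masks = np.empty((cfg.n_frames, size, size), dtype=np.uint8)
    ray_scale = np.sqrt(2.0 / np.pi)                  # unit-mean Rayleigh
    for k in range(cfg.n_frames):
        s = np.sqrt(areas[k] / ed_area)
        pool = _ellipse_mask(size, center, s * a0, s * b0, cfg.lv_tilt_deg)
        rim = _ellipse_mask(size, center, rim_scale * s * a0, rim_scale * s * b0,
                            cfg.lv_tilt_deg) & ~pool
        img = np.zeros((size, size), dtype=np.float64)
        img[sector] = cfg.tissue_intensity
        img[rim & sector] = cfg.myo_intensity
        img[pool] = cfg.pool_intensity
        if cfg.speckle_scale > 0:
            speckle = rng.rayleigh(scale=ray_scale, size=img.shape)
            img *= (1.0 - cfg.speckle_scale) + cfg.speckle_scale * speckle
        if cfg.blur_sigma > 0:
            img = gaussian_filter(img, cfg.blur_sigma)
        frames[k] = np.clip(img, 0.0, 1.0)
        masks[k] = pool.astype(np.uint8)

    px_areas = masks.reshape(cfg.n_frames, -1).sum(axis=1)
    return EchoSequence(frames=frames, masks=masks,
                        ed_index=int(px_areas.argmax()),
                        es_index=int(px_areas.argmin()),
                        true_ef=cfg.ef_target, seed=cfg.seed)


# ---------------------------------------------------------------------------
# datasets and the EchoNet-dialect manifest
# ---------------------------------------------------------------------------

def _split_counts(n: int, fracs) -> list[int]:
    """Largest-remainder apportionment; exact for divisible n."""
    raw = [n * f for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(rem):
        counts[order[i]] += 1
    return counts

def _contour_rows(mask: np.ndarray, frame: int, fname: str, n_pts: int = 21):
    """Paired-chord tracing rows: point i is paired with its opposite point
    on the closed contour, so (X1,Y1) walks one side of the boundary and
    (X2,Y2) the other — the chord convention the EchoNet CSVs use."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return []
    contour = max(contours, key=len)
    take = np.linspace(0, len(contour) - 1, 2 * n_pts).astype(int)
    pts = contour[take]                                  # (row, col)
    rows = []
    for i in range(n_pts):
        (y1, x1), (y2, x2) = pts[i], pts[2 * n_pts - 1 - i]
        rows.append({"FileName": fname, "X1": x1, "Y1": y1,
                     "X2": x2, "Y2": y2, "Frame": frame})
    return rows


def make_dataset(n_sequences: int, base_cfg: SynthConfig | None = None,
                 *, ef_range=(0.45, 0.75), seed: int = 0,
                 splits=(0.70, 0.15, 0.15)):
    """Generate a jittered cohort of sequences plus an EchoNet-style manifest.

    Returns ``(sequences, filelist, tracings)`` where ``filelist`` and
    ``tracings`` are DataFrames in the FileList.csv / VolumeTracings.csv
    dialect.  EF varies uniformly over ``ef_range``; geometry (centre,
    aspect, tilt, ED area) is jittered per sequence.  Splits are assigned
    by sequence with exact largest-remainder counts (TRAIN/VAL/TEST).
    """
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    base = (base_cfg or SynthConfig()).validate()
    rng = np.random.default_rng(seed)
    counts = _split_counts(n_sequences, splits)
    split_names = sum([[name] * c for name, c in
                      zip(("TRAIN", "VAL", "TEST"), counts)], [])

    sequences, fl_rows, tr_rows = [], [], []
    for i in range(n_sequences):
        cfg = dataclasses.replace(
            base,
            ef_target=float(rng.uniform(*ef_range)),
            ed_area_px=base.resolved_ed_area() * float(rng.uniform(0.8, 1.2)),
            lv_center=(base.lv_center[0] + float(rng.uniform(-0.03, 0.03)),
                       base.lv_center[1] + float(rng.uniform(-0.03, 0.03))),
            lv_aspect=base.lv_aspect * float(rng.uniform(0.88, 1.12)),
            lv_tilt_deg=float(rng.uniform(-8.0, 8.0)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        seq = make_sequence(cfg)
        fname = f"synth{i:04d}"
        sequences.append(seq)
        fl_rows.append({"FileName": fname, "EF": 100.0 * seq.true_ef,
                        "Split": split_names[i]})
        for frame in (seq.ed_index, seq.es_index):
            tr_rows.extend(_contour_rows(seq.masks[frame], frame, fname))
    return sequences, pd.DataFrame(fl_rows), pd.DataFrame(tr_rows)


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def write_sequence(seq: EchoSequence, out_dir) -> Path:
    """Write frames (8-bit grayscale PNG), masks (0/255 PNG) and metadata."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for k in range(seq.n_frames):
        frame8 = np.round(seq.frames[k] * 255.0).astype(np.uint8)
        iio.imwrite(out / "frames" / f"frame_{k:03d}.png", frame8)
        iio.imwrite(out / "masks" / f"mask_{k:03d}.png",
                    (seq.masks[k] * 255).astype(np.uint8))
    meta = {"n_frames": int(seq.n_frames), "ed_index": int(seq.ed_index),
            "es_index": int(seq.es_index), "true_ef": float(seq.true_ef),
            "seed": int(seq.seed),
            "shape": [int(s) for s in seq.frames.shape[1:]]}
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_sequence(in_dir) -> EchoSequence:
    """Inverse of :func:`write_sequence` (frames within 8-bit quantisation)."""
    src = Path(in_dir)
    try:
        meta = json.loads((src / "meta.json").read_text())
        frames = np.stack([
            iio.imread(src / "frames" / f"frame_{k:03d}.png")
            for k in range(meta["n_frames"])
        ]).astype(np.float32) / 255.0
        masks = np.stack([
            iio.imread(src / "masks" / f"mask_{k:03d}.png")
            for k in range(meta["n_frames"])
        ])
    except FileNotFoundError as exc:
        raise ValidationError(f"incomplete sequence directory {src}: {exc}") from exc
    return EchoSequence(frames=frames, masks=(masks > 127).astype(np.uint8),
                        ed_index=meta["ed_index"], es_index=meta["es_index"],
                        true_ef=meta["true_ef"], seed=meta["seed"])


def write_dataset(sequences, filelist: pd.DataFrame, tracings: pd.DataFrame,
                  out_dir) -> Path:
    """Write a full cohort: one directory per sequence plus the two CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, seq in zip(filelist["FileName"], sequences):
        write_sequence(seq, out / name)
    filelist.to_csv(out / "FileList.csv", index=False)
    tracings.to_csv(out / "VolumeTracings.csv", index=False)
    return out
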