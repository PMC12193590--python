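"""Ejection fraction from per-frame segmentation masks.

The segmented left-ventricular pixel area of each frame serves as the
volume proxy: end-diastole (ED) is the frame of maximal area, end-systole
(ES) the frame of minimal area, and

    EF = (EDV - ESV) / EDV

with EDV/ESV the proxy volumes at those frames.  Pixel area is a
single-plane proxy, not a clinical volume estimate (no Simpson biplane
reconstruction); it is exact for the synthetic cohort, whose ground truth
is defined the same way.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["EFReport", "lv_area", "select_ed_es", "ejection_fraction",
           "ef_from_masks", "ef_from_video", "reports_to_csv"]


@dataclass
class EFReport:
    """ED/ES frame selection, volume proxies and the resulting EF."""

    ed_index: int
    es_index: int
    edv: float                  # pixel-area proxy at end-diastole
    esv: float                  # pixel-area proxy at end-systole
    ef: float
    sequence_id: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def lv_area(mask) -> int:
    """Foreground pixel count of a binary mask."""
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"mask is not binary; values {vals[:8]}")
    return int(m.sum())


def select_ed_es(areas) -> tuple[int, int]:
    """ED = argmax, ES = argmin of the area series (earliest index on ties)."""
    a = np.asarray(areas, dtype=np.float64)
    if a.ndim != 1 or a.size < 2:
        raise ValidationError("need a 1-D series of at least 2 frame areas")
    if np.all(a == 0):
        raise ValidationError("no LV found in any frame (all areas zero)")
    return int(a.argmax()), int(a.argmin())


def ejection_fraction(edv: float, esv: float) -> float:
    """EF = (EDV - ESV) / EDV."""
    if edv <= 0:
        raise ValidationError("EDV must be positive to define EF")
    if esv < 0 or esv > edv:
        raise ValidationError(f"need 0 <= ESV <= EDV, got ESV={esv}, EDV={edv}")
    return (edv - esv) / edv


def ef_from_masks(masks, sequence_id: str = "") -> EFReport:
    """EF report from a (T, H, W) stack of binary masks."""
    areas = [lv_area(m) for m in np.asarray(masks)]
    ed, es = select_ed_es(areas)
    edv, esv = float(areas[ed]), float(areas[es])
    return EFReport(ed_index=ed, es_index=es, edv=edv, esv=esv,
                    ef=ejection_fraction(edv, esv), sequence_id=sequence_id)


def ef_from_video(model, frames, *, threshold: float = 0.5,
                  batch_size: int = 4, sequence_id: str = "") -> EFReport:
    """Segment every frame with ``model`` and derive the EF report.

    ``frames`` is (T, H, W) or (T, 1, H, W) grayscale in [0, 1]; the model's
    deepest head is binarised at ``threshold``.  Deterministic in eval mode.
    """
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4:
        raise ValidationError(f"expected (T,H,W) or (T,1,H,W) frames, got {arr.shape}")
    preds = []
    for lo in range(0, arr.shape[0], batch_size):
        probs = model.predict(arr[lo:lo + batch_size])
        preds.append((probs[:, 0] >= threshold).astype(np.uint8))
    masks = np.concatenate(preds, axis=0)
    if masks.sum() == 0:
        raise ValidationError("model predicted an empty LV in every frame")
    return ef_from_masks(masks, sequence_id=sequence_id)


def reports_to_csv(reports, path) -> pd.DataFrame:
    """Write EF reports as CSV (sequence_id, ed/es indices, proxies, EF)."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    df = df[["sequence_id", "ed_index", "es_index", "edv", "esv", "ef"]]
    df = df.rename(columns={"edv": "edv_px", "esv": "esv_px"})
    df.to_csv(path, index=False)
    return df
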