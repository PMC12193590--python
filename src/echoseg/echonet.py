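"""EchoNet-dialect annotation IO.

Reads the two CSV files used by the EchoNet-Dynamic distribution —
``FileList.csv`` (FileName, EF in percent, Split) and
``VolumeTracings.csv`` (FileName, X1, Y1, X2, Y2, Frame) — and rasterises a
frame's tracing rows to a binary mask.  Tracing rows are interpreted as
paired boundary points: the polygon is the (X1, Y1) point sequence followed
by the reversed (X2, Y2) sequence, filled with an even-odd scanline fill.
X is the column coordinate, Y the row, frames are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon

from .errors import ValidationError

__all__ = ["read_filelist", "read_volume_tracings", "rasterize_tracing",
           "masks_from_tracings"]

_FILELIST_COLS = {"FileName", "EF", "Split"}
_TRACING_COLS = {"FileName", "X1", "Y1", "X2", "Y2", "Frame"}


def read_filelist(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = _FILELIST_COLS - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: FileList.csv missing columns {sorted(missing)}")
    return df


def read_volume_tracings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = _TRACING_COLS - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: VolumeTracings.csv missing columns {sorted(missing)}")
    return df


def rasterize_tracing(rows: pd.DataFrame, height: int, width: int) -> np.ndarray:
    """Fill one frame's tracing rows into a (height, width) binary mask."""
    if len(rows) < 2:
        raise ValidationError("need at least 2 tracing rows to form a polygon")
    xs = np.concatenate([rows["X1"].to_numpy(), rows["X2"].to_numpy()[::-1]])
    ys = np.concatenate([rows["Y1"].to_numpy(), rows["Y2"].to_numpy()[::-1]])
    rr, cc = polygon(ys, xs, shape=(height, width))
    mask = np.zeros((height, width), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def masks_from_tracings(tracings: pd.DataFrame, file_name: str,
                        height: int, width: int) -> dict[int, np.ndarray]:
    """All annotated frames of one video as {frame_index: mask}."""
    sel = tracings[tracings["FileName"] == file_name]
    if sel.empty:
        raise ValidationError(f"no tracings for {file_name!r}")
    return {int(f): rasterize_tracing(g, height, width)
            for f, g in sel.groupby("Frame")}


def load_manifest(root) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read both manifest CSVs from a dataset directory."""
    root = Path(root)
    return (read_filelist(root / "FileList.csv"),
            read_volume_tracings(root / "VolumeTracings.csv"))
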