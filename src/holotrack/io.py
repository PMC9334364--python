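"""File I/O: TIFF hologram stacks, CSV tables, YAML run configuration.

Holograms are written as 32-bit float little-endian TIFF, one page per
frame, with the pixel pitch recorded in the TIFF resolution tags (advisory
only — the authoritative value lives in the config snapshot written next
to every output).  CSVs are UTF-8 with a mandatory header, '.' decimal
separator, lengths always in µm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import HologramFrame, TRUTH_COLUMNS

DETECTIONS_COLUMNS = ["frame", "object_id", "x_um", "y_um", "z_um", "area_px"]
TRACKS_COLUMNS = ["track_id", "frame", "x_um", "y_um", "z_um"]


def write_hologram_stack(
    path: str | Path, frames: list[HologramFrame], pixel_pitch_um: float | None = None
) -> None:
    """Write frames as a multi-page float32 TIFF."""
    data = np.stack([np.asarray(f.intensity, dtype=np.float32) for f in frames])
    kwargs = {}
    if pixel_pitch_um is not None:
        # resolution tags are pixels per centimetre
        res = 1e4 / pixel_pitch_um
        kwargs = {"resolution": (res, res), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(path, data, byteorder="<", photometric="minisblack", **kwargs)


def read_hologram_stack(path: str | Path) -> list[HologramFrame]:
    """Read a multi-page TIFF back into hologram frames."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return [HologramFrame(np.asarray(page, dtype=float), i) for i, page in enumerate(data)]


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns {sorted(missing)}")
    return df


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTIONS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns {sorted(missing)}")
    return df


def write_config_snapshot(path: str | Path, resolved: dict) -> None:
    """Record the fully resolved configuration (incl. seed) beside outputs."""
    Path(path).write_text(json.dumps(resolved, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"real": obj.real, "imag": obj.imag}
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    return str(obj)
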