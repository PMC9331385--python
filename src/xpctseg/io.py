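"""Volume I/O: multipage TIFF stacks with YAML sidecar metadata.

Grayscale volumes are written as 32-bit float, label volumes as 8-bit
unsigned, one page per slice, axes (z, y, x) with z the tomographic
rotation axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml


def save_volume(path: str | Path, data: np.ndarray, pixel_size: float | None = None,
                meta: dict | None = None) -> None:
    """Write a 3D array as a multipage TIFF (float32 for grayscale,
    uint8 for integer labels) with an optional ``.yaml`` sidecar."""
    path = Path(path)
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("label volumes must fit in uint8")
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    sidecar = dict(meta or {})
    if pixel_size is not None:
        sidecar["pixel_size_um"] = float(pixel_size)
    if sidecar:
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(_plain(sidecar), fh, sort_keys=False)


def load_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multipage TIFF; returns (array, sidecar metadata dict)."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return arr, meta


def _plain(obj):
    """Recursively convert dataclasses / numpy scalars to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
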