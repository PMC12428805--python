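"""Reading and writing of slabs, displacement fields and sidecar metadata.

Images travel as 8/16-bit grayscale PNG or TIFF plus a JSON sidecar
(``<image>.json``) carrying physical scale and labels; displacement fields
as 2-channel 32-bit float TIFF (channel 0 = dx, channel 1 = dy, px units)
with their own sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import DEFAULT_SCAN_WIDTH_MM, DisplacementField, EnFaceSlab

__all__ = ["save_slab", "load_slab", "save_field", "load_field"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_slab(path, slab: EnFaceSlab, bit_depth: int = 16, extra: Optional[dict] = None) -> Path:
    """Write a slab as grayscale PNG/TIFF plus a JSON sidecar."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(slab.pixels * 255.0, 0, 255).round().astype(np.uint8)
    elif bit_depth == 16:
        arr = np.clip(slab.pixels * 65535.0, 0, 65535).round().astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    meta = {
        "scan_width_mm": slab.scan_width_mm,
        "slab": slab.slab,
        "timepoint": slab.timepoint,
        "bit_depth": bit_depth,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_slab(path) -> EnFaceSlab:
    """Read a grayscale raster and its sidecar back into an EnFaceSlab."""
    path = Path(path)
    arr = np.asarray(iio.imread(path) if path.suffix.lower() not in (".tif", ".tiff") else tifffile.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return EnFaceSlab(
        np.clip(arr.astype(np.float64), 0.0, 1.0),
        scan_width_mm=float(meta.get("scan_width_mm", DEFAULT_SCAN_WIDTH_MM)),
        slab=meta.get("slab"),
        timepoint=meta.get("timepoint"),
    )


def save_field(path, field: DisplacementField, um_per_px: float, extra: Optional[dict] = None) -> Path:
    """Write a displacement field as 2-channel float32 TIFF + sidecar."""
    path = Path(path)
    stack = np.stack([field.dx, field.dy]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {"um_per_px": um_per_px, "channels": ["dx", "dy"], "units": "px"}
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    np.save(str(path) + ".mask.npy", field.valid_mask)
    return path


def load_field(path) -> tuple[DisplacementField, dict]:
    """Read a displacement field and its sidecar metadata."""
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    if stack.shape[0] != 2:
        raise ValueError("expected a 2-channel (dx, dy) field")
    mask_path = Path(str(path) + ".mask.npy")
    mask = np.load(mask_path) if mask_path.exists() else None
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return DisplacementField(stack[0], stack[1], mask), meta
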