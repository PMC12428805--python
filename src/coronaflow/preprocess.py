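"""Image standardization before motion estimation.

Grayscale conversion and local (tiled, contrast-limited) histogram
equalization.  Both images of a pair are equalized independently.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skimage import exposure

from .core import DEFAULT_SCAN_WIDTH_MM, EnFaceSlab

#: Rec. 709 luminance weights used to collapse RGB rasters.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

DEFAULT_TILE_GRID = 8
DEFAULT_CLIP_LIMIT = 0.01


def to_grayscale(
    raster: np.ndarray,
    scan_width_mm: float = DEFAULT_SCAN_WIDTH_MM,
    slab: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> EnFaceSlab:
    """Collapse a 1- or 3-channel raster to a grayscale slab in ``[0, 1]``.

    Integer inputs are rescaled by their dtype range; float inputs are
    assumed to already be in ``[0, 1]``.
    """
    arr = np.asarray(raster)
    if arr.size == 0:
        raise ValueError("empty raster")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected 3-channel raster, got shape {arr.shape}")
        arr = arr[:, :, :3] @ LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"expected 2D or 3D raster, got ndim={arr.ndim}")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"raster must be square, got {arr.shape}")
    return EnFaceSlab(np.clip(arr, 0.0, 1.0), scan_width_mm=scan_width_mm, slab=slab, timepoint=timepoint)


def local_hist_eq(
    img: EnFaceSlab,
    tile_px: Optional[int] = None,
    clip: float = DEFAULT_CLIP_LIMIT,
) -> EnFaceSlab:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``tile_px`` is the side of the local tile; the default divides the image
    into an 8x8 tile grid.  Deterministic; output in ``[0, 1]``.
    """
    n = img.width_px
    if tile_px is None:
        tile_px = max(2, n // DEFAULT_TILE_GRID)
    if tile_px <= 1:
        raise ValueError("tile_px must be > 1")
    if n // tile_px < 4:
        raise ValueError("tile_px must allow at least a 4x4 tile grid")
    if not 0 < clip <= 1:
        raise ValueError("clip must be in (0, 1]")
    px = img.pixels
    if px.max() - px.min() < 1e-12:
        # no contrast to equalize
        return img.with_pixels(px.copy())
    out = exposure.equalize_adapthist(px, kernel_size=tile_px, clip_limit=clip)
    return img.with_pixels(np.clip(out, 0.0, 1.0))
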