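"""Rendering of displacement results: vector overlays and deformation maps.

Conventions match the reported output: yellow arrows whose length is
proportional to the vector magnitude, and a blue-to-red color-coded
deformation map on a fixed 0-90 micrometer scale (red = greatest).
Rendering is pure numpy -> byte-identical output for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from skimage.draw import line as draw_line

from .core import EnFaceSlab
from .registration import GridDisplacement

__all__ = ["RenderConfig", "DEFORMATION_CMAP", "render_overlay", "render_magnitude"]

#: Blue -> cyan -> yellow -> red; red channel is monotone non-decreasing so
#: "red = greatest displacement" holds pointwise.
DEFORMATION_CMAP = LinearSegmentedColormap.from_list(
    "deformation", ["#00007f", "#0000ff", "#00ffff", "#ffff00", "#ff7f00", "#ff0000"]
)

YELLOW = (255, 255, 0)


@dataclass(frozen=True)
class RenderConfig:
    arrow_stride: int = 2
    arrow_color: Tuple[int, int, int] = YELLOW
    cmap_range_um: Tuple[float, float] = (0.0, 90.0)
    scale_bar: bool = True
    arrow_px_per_um: float = 0.5

    def __post_init__(self) -> None:
        if self.arrow_stride < 1:
            raise ValueError("arrow_stride must be >= 1")
        if self.cmap_range_um[0] >= self.cmap_range_um[1]:
            raise ValueError("cmap_range lower bound must be < upper bound")
        if self.arrow_px_per_um <= 0:
            raise ValueError("arrow_px_per_um must be > 0")


def _draw_segment(rgb: np.ndarray, p0, p1, color) -> None:
    h, w = rgb.shape[:2]
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = draw_line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rgb[rr[keep], cc[keep]] = color


def render_overlay(slab: EnFaceSlab, grid: GridDisplacement, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Slab image with yellow displacement arrows at subsampled grid nodes.

    Arrow length is ``|d|`` in micrometers times ``cfg.arrow_px_per_um``.
    Returns an RGB uint8 array.
    """
    if grid.image_shape != slab.pixels.shape:
        raise ValueError("grid geometry does not match the slab image")
    base = np.clip(slab.pixels * 255.0, 0, 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    um_per_px = slab.um_per_px
    s = cfg.arrow_stride
    for i in range(0, grid.n_side, s):
        for j in range(0, grid.n_side, s):
            if not grid.valid[i, j]:
                continue
            node = grid.nodes[i, j]
            vec_um = grid.vectors[i, j] * um_per_px
            length_px = float(np.hypot(*vec_um)) * cfg.arrow_px_per_um
            if length_px < 0.5:
                continue
            direction = vec_um / np.hypot(*vec_um)
            tip = node + direction * length_px
            _draw_segment(rgb, node, tip, cfg.arrow_color)
            # arrowhead: two barbs at +-150 degrees from the shaft direction
            head = min(3.0, 0.4 * length_px)
            for sign in (1.0, -1.0):
                ang = np.deg2rad(150.0) * sign
                rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                _draw_segment(rgb, tip, tip + rot @ direction * head, cfg.arrow_color)
    return rgb


def render_magnitude(mag_map_um: np.ndarray, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Color-coded deformation map with an optional legend strip.

    Values are clipped to ``cfg.cmap_range_um`` (default 0-90 um) and mapped
    blue -> red; values at or above the top of the range render pure red.
    Returns an RGB uint8 array.
    """
    mag = np.asarray(mag_map_um, dtype=np.float64)
    if not np.all(np.isfinite(mag)):
        raise ValueError("magnitude map must be finite")
    lo, hi = cfg.cmap_range_um
    norm = (np.clip(mag, lo, hi) - lo) / (hi - lo)
    rgba = DEFORMATION_CMAP(norm)
    rgb = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    if cfg.scale_bar:
        w = rgb.shape[1]
        ramp = DEFORMATION_CMAP(np.linspace(0, 1, w))[:, :3]
        strip = (np.tile(ramp[None, :, :], (12, 1, 1)) * 255.0).round().astype(np.uint8)
        sep = np.zeros((2, w, 3), dtype=np.uint8)
        rgb = np.concatenate([rgb, sep, strip], axis=0)
    return rgb
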