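"""Core data structures shared across the pipeline.

Coordinate convention (fixed throughout the package): ``x`` is the column
index increasing rightward, ``y`` is the row index increasing downward, and
the origin sits at the centre of the top-left pixel.  Displacement fields map
the reference image onto the moving image (a feature at ``p`` in the
reference appears at ``p + d(p)`` in the moving image).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SLABS = ("SCP", "DCP", "CC")
TIMEPOINTS = ("T0", "T6")

DEFAULT_SCAN_WIDTH_MM = 3.0


@dataclass(frozen=True)
class EnFaceSlab:
    """A single grayscale en-face angiogram with physical scale metadata.

    Parameters
    ----------
    pixels
        2D float array with values in ``[0, 1]``.  Must be square.
    scan_width_mm
        Physical width of the field of view (default 3.0 mm, fovea-centred).
    slab
        One of ``SCP``, ``DCP``, ``CC`` (or ``None`` for anonymous images).
    timepoint
        ``T0`` or ``T6`` (or ``None``).
    """

    pixels: np.ndarray
    scan_width_mm: float = DEFAULT_SCAN_WIDTH_MM
    slab: Optional[str] = None
    timepoint: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if px.shape[0] != px.shape[1]:
            raise ValueError(f"en-face slab must be square, got {px.shape}")
        if px.size == 0:
            raise ValueError("empty raster")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if self.scan_width_mm <= 0:
            raise ValueError("scan_width_mm must be positive")
        if self.slab is not None and self.slab not in SLABS:
            raise ValueError(f"unknown slab {self.slab!r}")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def um_per_px(self) -> float:
        return 1000.0 * self.scan_width_mm / self.width_px

    @property
    def center(self) -> np.ndarray:
        """Image centre ``(cx, cy)`` in pixel coordinates."""
        return np.array([(self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0])

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceSlab":
        return replace(self, pixels=pixels)


@dataclass
class DisplacementField:
    """Dense per-pixel displacement ``(dx, dy)`` in pixel units.

    ``valid_mask`` marks pixels where the estimate is trustworthy (border
    regions and singular pixels are excluded).
    """

    dx: np.ndarray
    dy: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must have the same shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.dx.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.dx.shape:
                raise ValueError("valid_mask shape mismatch")
        bad = ~np.isfinite(self.dx) | ~np.isfinite(self.dy)
        if np.any(bad & self.valid_mask):
            raise ValueError("non-finite displacement at valid pixels")

    @property
    def shape(self) -> tuple:
        return self.dx.shape

    def magnitude_px(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the image centre plus translation, in pixel units.

    Acts on a point ``p`` as ``R(theta) @ (p - c) + c + t`` where ``c`` is the
    image centre.  Because the centre is shared, composition and inversion are
    closed-form in the ``(theta, tx, ty)`` parameterization.
    """

    theta_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.theta_deg) >= 45.0:
            raise ValueError("|theta| must be < 45 degrees")

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 2)`` array of ``(x, y)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        center = np.asarray(center, dtype=np.float64)
        out = (pts - center) @ self.rotation_matrix.T + center
        out += np.array([self.tx, self.ty])
        return out if np.asarray(points).ndim > 1 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map ``self o other`` (apply ``other`` first)."""
        t_other = np.array([other.tx, other.ty])
        t_new = self.rotation_matrix @ t_other + np.array([self.tx, self.ty])
        return RigidTransform(self.theta_deg + other.theta_deg, t_new[0], t_new[1])

    def inverse(self) -> "RigidTransform":
        t = np.array([self.tx, self.ty])
        t_inv = -self.rotation_matrix.T @ t
        return RigidTransform(-self.theta_deg, t_inv[0], t_inv[1])

    @property
    def is_identity(self) -> bool:
        return self.theta_deg == 0.0 and self.tx == 0.0 and self.ty == 0.0
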