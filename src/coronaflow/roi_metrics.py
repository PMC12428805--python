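"""Whole-image and concentric-ROI displacement statistics in micrometers.

Statistics are computed over the 36x36 reporting grid: for each region the
mean and SD of node-wise displacement magnitudes ``D = sqrt(Dx^2 + Dy^2)``
(converted to micrometers) are returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import EnFaceSlab
from .registration import GridDisplacement

__all__ = ["ROISpec", "DisplacementSummary", "roi_mask", "summarize", "summaries_to_frame"]

DEFAULT_RADII_MM = (0.5, 0.75, 1.5)


@dataclass(frozen=True)
class ROISpec:
    """Concentric circular regions centred on the foveola.

    ``center_px`` defaults to the image centre (scans are fovea-centred).
    """

    radii_mm: Tuple[float, ...] = DEFAULT_RADII_MM
    center_px: Optional[Tuple[float, float]] = None
    whole_image: bool = True

    def __post_init__(self) -> None:
        radii = tuple(self.radii_mm)
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be positive")
        if list(radii) != sorted(radii):
            raise ValueError("radii must be increasing")
        object.__setattr__(self, "radii_mm", radii)

    def center_for(self, img: EnFaceSlab) -> np.ndarray:
        if self.center_px is not None:
            return np.asarray(self.center_px, dtype=np.float64)
        return img.center

    def roi_labels(self) -> List[str]:
        labels = ["whole"] if self.whole_image else []
        labels += [f"r{r:g}" for r in self.radii_mm]
        return labels


@dataclass
class DisplacementSummary:
    """Mean/SD displacement for one region of one slab pair."""

    slab: Optional[str]
    roi: str
    mean_um: float
    sd_um: float
    n_nodes: int
    timepair: str = "T0-T6"


def roi_mask(spec: ROISpec, radius_mm: float, img_meta: EnFaceSlab, grid: GridDisplacement) -> np.ndarray:
    """Boolean inclusion mask over grid nodes for one circular region.

    A node is included iff its distance from the foveal centre, in
    micrometers, is at most ``radius_mm * 1000`` (inclusive boundary).
    """
    if radius_mm > img_meta.scan_width_mm / 2.0 + 1e-12:
        raise ValueError(f"radius {radius_mm} mm exceeds the {img_meta.scan_width_mm} mm field half-width")
    center = spec.center_for(img_meta)
    d_px = np.linalg.norm(grid.nodes - center, axis=-1)
    return d_px * img_meta.um_per_px <= radius_mm * 1000.0 + 1e-9


def summarize(
    grid: GridDisplacement,
    spec: ROISpec,
    meta: EnFaceSlab,
    timepair: str = "T0-T6",
) -> List[DisplacementSummary]:
    """Per-ROI mean and SD of node displacement magnitudes in micrometers.

    ``grid`` must be sampled from the residual field after rigid alignment.
    """
    mags_um = np.linalg.norm(grid.vectors, axis=-1) * meta.um_per_px
    out: List[DisplacementSummary] = []

    def _one(label: str, include: np.ndarray) -> None:
        sel = include & grid.valid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {label!r} contains no valid grid nodes")
        vals = mags_um[sel]
        out.append(
            DisplacementSummary(
                slab=meta.slab,
                roi=label,
                mean_um=float(vals.mean()),
                sd_um=float(vals.std(ddof=1)) if n > 1 else 0.0,
                n_nodes=n,
                timepair=timepair,
            )
        )

    if spec.whole_image:
        _one("whole", np.ones(grid.valid.shape, dtype=bool))
    for r in spec.radii_mm:
        _one(f"r{r:g}", roi_mask(spec, r, meta, grid))
    return out


def summaries_to_frame(summaries: Sequence[DisplacementSummary]) -> pd.DataFrame:
    """Stack summaries into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "slab": s.slab,
                "roi": s.roi,
                "mean_um": s.mean_um,
                "sd_um": s.sd_um,
                "n_nodes": s.n_nodes,
                "timepair": s.timepair,
            }
            for s in summaries
        ]
    )
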