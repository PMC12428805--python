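"""Pipeline configuration: every tunable in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .flow import FlowParams
from .preprocess import DEFAULT_CLIP_LIMIT

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All module parameters, round-trippable through YAML."""

    # preprocess
    tile_px: Optional[int] = None  # None -> 1/8 of the image side
    clip_limit: float = DEFAULT_CLIP_LIMIT
    equalize: bool = True
    # flow
    sigma_app: float = 1.5
    agg_window: float = 4.0
    n_iter: int = 3
    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    # alignment
    tol: float = 0.03
    max_iter: int = 50
    n_side: int = 36
    # ROI metrics
    radii_mm: Tuple[float, ...] = (0.5, 0.75, 1.5)
    scan_width_mm: float = 3.0
    # reproducibility
    seed: int = 0

    @property
    def flow_params(self) -> FlowParams:
        return FlowParams(
            sigma_app=self.sigma_app,
            agg_window=self.agg_window,
            n_iter=self.n_iter,
            pyramid_levels=self.pyramid_levels,
            pyramid_scale=self.pyramid_scale,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radii_mm"] = list(d["radii_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "radii_mm" in d:
            d["radii_mm"] = tuple(d["radii_mm"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
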