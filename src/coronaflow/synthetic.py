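"""Synthetic angiogram pairs and cohorts with known ground truth.

Everything downstream (alignment, flow, ROI statistics, mixed models) is
exercised on images produced here, so each generator records the exact warp
or cohort parameters it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DEFAULT_SCAN_WIDTH_MM, SLABS, DisplacementField, EnFaceSlab, RigidTransform

__all__ = [
    "SlabStyle",
    "GroundTruthWarp",
    "CohortSpec",
    "WarpResult",
    "SLAB_STYLES",
    "generate_slab_image",
    "make_elastic_field",
    "apply_warp",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SlabStyle:
    """Visual recipe for one vascular slab."""

    name: str
    vessel_density: float
    caliber_px: float
    texture: str  # branching | mesh | granular

    def __post_init__(self) -> None:
        if not 0.0 < self.vessel_density < 0.6:
            raise ValueError("vessel_density must be in (0, 0.6)")
        if self.caliber_px < 1:
            raise ValueError("caliber_px must be >= 1")
        if self.texture not in ("branching", "mesh", "granular"):
            raise ValueError(f"unknown texture {self.texture!r}")


#: Default styles: large branching vessels in the superficial plexus, a fine
#: capillary mesh in the deep plexus, granular high-frequency texture in the
#: choriocapillaris.
SLAB_STYLES: Dict[str, SlabStyle] = {
    "SCP": SlabStyle("SCP", vessel_density=0.30, caliber_px=3.0, texture="branching"),
    "DCP": SlabStyle("DCP", vessel_density=0.40, caliber_px=1.5, texture="mesh"),
    "CC": SlabStyle("CC", vessel_density=0.50, caliber_px=1.0, texture="granular"),
}


def _branching_canvas(rng: np.random.Generator, size: int, density: float, caliber: float) -> np.ndarray:
    """Random-walk vessel strokes with occasional branching, dilated to caliber."""
    path = np.zeros((size, size), dtype=bool)
    radius = max(1, int(round(caliber / 2)))
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    disk = (xx ** 2 + yy ** 2) <= radius ** 2
    target = density * size * size
    # each path pixel covers roughly the disk footprint after dilation
    approx_px_per_step = max(1.0, caliber)
    budget = int(target / approx_px_per_step)
    stack = []
    drawn = 0
    while drawn < budget:
        if stack:
            pos, ang = stack.pop()
        else:
            pos = rng.uniform(0, size, size=2)
            ang = rng.uniform(0, 2 * np.pi)
        steps = int(rng.integers(size // 4, size))
        for _ in range(steps):
            ang += rng.normal(0, 0.15)
            pos = pos + np.array([np.cos(ang), np.sin(ang)])
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                break
            path[int(pos[1]), int(pos[0])] = True
            drawn += 1
            if rng.random() < 0.01:
                stack.append((pos.copy(), ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)))
            if drawn >= budget:
                break
    mask = ndimage.binary_dilation(path, structure=disk)
    img = ndimage.gaussian_filter(mask.astype(np.float64), sigma=caliber / 3)
    return img


def _mesh_canvas(rng: np.random.Generator, size: int, density: float, caliber: float) -> np.ndarray:
    """Capillary mesh: zero-crossing web of band-pass filtered noise."""
    noise = rng.standard_normal((size, size))
    low = ndimage.gaussian_filter(noise, sigma=2.5 * caliber)
    band = low - ndimage.gaussian_filter(noise, sigma=5.0 * caliber)
    band /= band.std() + 1e-12
    # pixels near the zero level set form a connected net
    thr = np.quantile(np.abs(band), density)
    mask = np.abs(band) <= thr
    img = ndimage.gaussian_filter(mask.astype(np.float64), sigma=caliber / 3)
    return img


def _granular_canvas(rng: np.random.Generator, size: int, density: float, caliber: float) -> np.ndarray:
    """High-frequency granular texture (choriocapillaris style)."""
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=max(0.6, caliber / 2))
    thr = np.quantile(smooth, 1.0 - density)
    mask = smooth >= thr
    img = ndimage.gaussian_filter(mask.astype(np.float64), sigma=0.5)
    return img


def generate_slab_image(
    style: SlabStyle,
    size_px: int = 304,
    seed: int = 0,
    scan_width_mm: float = DEFAULT_SCAN_WIDTH_MM,
    timepoint: Optional[str] = None,
) -> EnFaceSlab:
    """Generate one synthetic en-face angiogram with the given slab texture.

    Deterministic given ``(style, size_px, seed)``.
    """
    if size_px < 128:
        raise ValueError("size_px must be >= 128")
    if size_px < 8 * style.caliber_px:
        raise ValueError("size_px too small to host caliber_px")
    rng = np.random.default_rng(seed)
    if style.texture == "branching":
        img = _branching_canvas(rng, size_px, style.vessel_density, style.caliber_px)
    elif style.texture == "mesh":
        img = _mesh_canvas(rng, size_px, style.vessel_density, style.caliber_px)
    else:
        img = _granular_canvas(rng, size_px, style.vessel_density, style.caliber_px)
    # faint background speckle so flat regions still carry gradient information
    img = 0.9 * img + 0.08 * ndimage.gaussian_filter(rng.standard_normal((size_px, size_px)), 1.0)
    img -= img.min()
    peak = img.max()
    if peak > 0:
        img /= peak
    name = style.name if style.name in SLABS else None
    return EnFaceSlab(np.clip(img, 0.0, 1.0), scan_width_mm=scan_width_mm, slab=name, timepoint=timepoint)


def make_elastic_field(
    size_px: int,
    mean_um: float,
    seed: int,
    smooth_px: float = 15.0,
) -> np.ndarray:
    """Smooth random displacement field in micrometers, shape ``(2, h, w)``.

    Gaussian-smoothed white noise per component with its best-fit rigid
    (rotation + translation) component projected out, rescaled so the mean
    vector magnitude equals ``mean_um`` exactly.  Removing the rigid part
    keeps the acquisition-misalignment / biological-displacement
    decomposition identifiable.  Correlation length ~ ``smooth_px``.
    """
    if mean_um < 0:
        raise ValueError("mean_um must be >= 0")
    rng = np.random.default_rng(seed)
    comps = rng.standard_normal((2, size_px, size_px))
    ex = ndimage.gaussian_filter(comps[0], sigma=smooth_px, mode="reflect")
    ey = ndimage.gaussian_filter(comps[1], sigma=smooth_px, mode="reflect")

    # project out the linearized rigid field theta * J (p - c) + t
    ys, xs = np.mgrid[0:size_px, 0:size_px].astype(np.float64)
    c = (size_px - 1) / 2.0
    rx, ry = xs - c, ys - c  # already zero-mean
    jx, jy = -ry, rx  # 90-degree rotation of the radius vector
    ex_c, ey_c = ex - ex.mean(), ey - ey.mean()
    theta = (jx * ex_c + jy * ey_c).sum() / (jx ** 2 + jy ** 2).sum()
    ex = ex_c - theta * jx
    ey = ey_c - theta * jy

    mag = np.hypot(ex, ey)
    scale = mean_um / (mag.mean() + 1e-300)
    return np.stack([ex * scale, ey * scale])


@dataclass(frozen=True)
class GroundTruthWarp:
    """Rigid misalignment composed with a smooth elastic field.

    Forward convention: content at reference position ``p`` moves to
    ``W(p) = E(R(p))`` in the second acquisition, where ``R`` is the rigid
    map (rotation ``theta`` about the image centre plus translation ``t`` in
    px) and ``E(q) = q + elastic(q)`` with ``elastic`` in px.
    """

    theta: float = 0.0
    t: Tuple[float, float] = (0.0, 0.0)
    elastic_um: Optional[np.ndarray] = None  # (2, h, w), micrometers
    mean_elastic_um: float = 0.0

    @classmethod
    def create(
        cls,
        theta: float = 0.0,
        t: Tuple[float, float] = (0.0, 0.0),
        mean_elastic_um: float = 0.0,
        size_px: int = 304,
        seed: int = 0,
        smooth_px: float = 15.0,
    ) -> "GroundTruthWarp":
        elastic = make_elastic_field(size_px, mean_elastic_um, seed, smooth_px) if mean_elastic_um > 0 else None
        return cls(theta=theta, t=tuple(t), elastic_um=elastic, mean_elastic_um=mean_elastic_um)

    def validate(self, size_px: int) -> None:
        if abs(self.theta) > 10.0:
            raise ValueError("|theta| must be <= 10 degrees to keep content in frame")
        if max(abs(self.t[0]), abs(self.t[1])) > 0.05 * size_px:
            raise ValueError("|t| must be <= 5% of image width")
        if self.elastic_um is not None and self.elastic_um.shape[1:] != (size_px, size_px):
            raise ValueError("elastic field shape does not match image")

    @property
    def rigid(self) -> RigidTransform:
        return RigidTransform(self.theta, self.t[0], self.t[1])

    @property
    def is_trivial(self) -> bool:
        no_elastic = self.elastic_um is None or not np.any(self.elastic_um)
        return self.theta == 0.0 and self.t == (0.0, 0.0) and no_elastic


@dataclass
class WarpResult:
    """Warped image plus the exact forward displacement it was built from."""

    image: EnFaceSlab
    true_field: DisplacementField


def _sample_vec(field: np.ndarray, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Bilinear sample of a (2, h, w) vector field at (x, y) px positions."""
    coords = np.stack([y.ravel(), x.ravel()])
    fx = ndimage.map_coordinates(field[0], coords, order=1, mode="reflect").reshape(x.shape)
    fy = ndimage.map_coordinates(field[1], coords, order=1, mode="reflect").reshape(x.shape)
    return fx, fy


def apply_warp(
    img: EnFaceSlab,
    warp: GroundTruthWarp,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> WarpResult:
    """Resample ``img`` under the rigid-then-elastic warp, with optional noise.

    Returns the warped image and the exact ground-truth displacement field
    ``d(p) = W(p) - p`` on the reference pixel grid.
    """
    size = img.width_px
    warp.validate(size)
    h, w = img.pixels.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    center = img.center
    elastic_px = None
    if warp.elastic_um is not None:
        elastic_px = warp.elastic_um / img.um_per_px

    rigid = warp.rigid

    # ground-truth forward displacement: W(p) - p with W = E o R
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    q = rigid.apply(pts, center)
    qx, qy = q[:, 0].reshape(h, w), q[:, 1].reshape(h, w)
    if elastic_px is not None:
        ex, ey = _sample_vec(elastic_px, qx, qy)
        wx, wy = qx + ex, qy + ey
    else:
        wx, wy = qx, qy
    true_field = DisplacementField(wx - xs, wy - ys)

    if warp.is_trivial and noise_sd == 0.0:
        return WarpResult(img.with_pixels(img.pixels.copy()), true_field)

    # inverse map for resampling: out(x) = img(W^{-1}(x))
    if elastic_px is not None:
        # fixed-point inversion of E: q such that q + e(q) = x
        ix, iy = xs.copy(), ys.copy()
        for _ in range(8):
            ex, ey = _sample_vec(elastic_px, ix, iy)
            ix, iy = xs - ex, ys - ey
    else:
        ix, iy = xs, ys
    inv = rigid.inverse()
    p = inv.apply(np.stack([ix.ravel(), iy.ravel()], axis=1), center)
    px, py = p[:, 0].reshape(h, w), p[:, 1].reshape(h, w)
    out = ndimage.map_coordinates(img.pixels, np.stack([py.ravel(), px.ravel()]), order=1, mode="reflect").reshape(h, w)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0, noise_sd, out.shape)
    return WarpResult(img.with_pixels(np.clip(out, 0.0, 1.0)), true_field)


PHENOTYPES = ("rpd", "dped", "drusen", "irora")


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a per-eye/per-slab displacement cohort.

    ``y[i, slab] = slab_mean + phenotype effects + u_i + eps`` with
    ``u_i ~ N(0, patient_sd^2)``, ``eps ~ N(0, residual_sd^2)``, truncated
    at zero (displacement magnitudes are nonnegative).
    """

    n_patients: int
    slab_means_um: Mapping[str, float]
    patient_sd_um: float = 0.0
    residual_sd_um: float = 0.0
    phenotype_rates: Mapping[str, float] = field(default_factory=dict)
    phenotype_effects_um: Mapping[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.patient_sd_um < 0 or self.residual_sd_um < 0:
            raise ValueError("SDs must be >= 0")
        for slab in self.slab_means_um:
            if slab not in SLABS:
                raise ValueError(f"unknown slab {slab!r}")
        for ph, rate in self.phenotype_rates.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {ph!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("phenotype rates must be in [0, 1]")


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a long-format cohort table from the spec's generative model.

    Columns: patient_id, eye_id, slab, roi, displacement_um,
    rpd, dped, drusen, irora.
    """
    rng = np.random.default_rng(seed)
    rows = []
    slabs = [s for s in SLABS if s in spec.slab_means_um]
    for i in range(spec.n_patients):
        flags = {ph: bool(rng.random() < spec.phenotype_rates.get(ph, 0.0)) for ph in PHENOTYPES}
        u = rng.normal(0.0, spec.patient_sd_um) if spec.patient_sd_um > 0 else 0.0
        for slab in slabs:
            y = spec.slab_means_um[slab] + u
            for ph in PHENOTYPES:
                if flags[ph]:
                    y += spec.phenotype_effects_um.get((ph, slab), 0.0)
            if spec.residual_sd_um > 0:
                y += rng.normal(0.0, spec.residual_sd_um)
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "eye_id": f"E{i:03d}",
                    "slab": slab,
                    "roi": "whole",
                    "displacement_um": max(0.0, y),
                    **flags,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "eye_id", "slab", "roi", "displacement_um", *PHENOTYPES])
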