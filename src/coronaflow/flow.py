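"""Dense two-frame motion estimation via quadratic polynomial expansion.

Each local neighborhood of the image is approximated by a quadratic model
``f(x) ~ x^T A x + b^T x + c`` fitted under a Gaussian applicability weight.
The displacement between two frames is then solved from the relation between
the two expansions, aggregated over a Gaussian neighborhood, iterated and
run coarse-to-fine over an image pyramid.

Coordinates: ``x`` = column, ``y`` = row (see :mod:`coronaflow.core`).
Flow maps the reference onto the moving image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core import DisplacementField, EnFaceSlab

__all__ = ["PolyExpansion", "FlowParams", "polynomial_expansion", "estimate_flow", "magnitude"]

_DET_EPS = 1e-12


@dataclass
class PolyExpansion:
    """Per-pixel quadratic model coefficients.

    ``f(p + w) ~ c(p) + b(p)^T w + w^T A(p) w`` for offsets ``w = (x, y)``.
    """

    a11: np.ndarray  # A[0,0] (x^2 coefficient)
    a12: np.ndarray  # A[0,1] = A[1,0]
    a22: np.ndarray  # A[1,1] (y^2 coefficient)
    bx: np.ndarray
    by: np.ndarray
    c: np.ndarray
    sigma_app: float = 1.5

    @property
    def A(self) -> np.ndarray:
        """Symmetric 2x2 matrix per pixel, shape (h, w, 2, 2)."""
        return np.stack(
            [
                np.stack([self.a11, self.a12], axis=-1),
                np.stack([self.a12, self.a22], axis=-1),
            ],
            axis=-2,
        )

    @property
    def b(self) -> np.ndarray:
        """Linear coefficient per pixel, shape (h, w, 2) as (bx, by)."""
        return np.stack([self.bx, self.by], axis=-1)


@dataclass(frozen=True)
class FlowParams:
    """Tuning knobs for the dense flow estimator."""

    sigma_app: float = 1.5
    agg_window: float = 4.0
    n_iter: int = 3
    pyramid_levels: int = 3
    pyramid_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_app <= 0:
            raise ValueError("sigma_app must be > 0")
        if self.agg_window <= 0:
            raise ValueError("agg_window must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not 0 < self.pyramid_scale < 1:
            raise ValueError("pyramid_scale must be in (0, 1)")


def polynomial_expansion(img, sigma_app: float = 1.5) -> PolyExpansion:
    """Fit the local quadratic model at every pixel by separable correlation.

    The weighted-least-squares normal matrix is identical at every pixel
    (uniform certainty), so the fit reduces to six separable correlations of
    the image with applicability-weighted basis kernels followed by one
    constant 6x6 solve.
    """
    if sigma_app <= 0:
        raise ValueError("sigma_app must be > 0")
    f = img.pixels if isinstance(img, EnFaceSlab) else np.asarray(img, dtype=np.float64)

    n = max(1, int(np.ceil(3.0 * sigma_app)))
    x = np.arange(-n, n + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma_app ** 2))

    # basis ordering: 1, x, y, x^2, y^2, xy
    kern_x = {0: g, 1: g * x, 2: g * x ** 2}
    # G = sum_w a(w) b(w) b(w)^T, separable into 1D moments
    m = {k: float(np.sum(g * x ** k)) for k in range(5)}

    def G_entry(px_, py_, qx_, qy_):
        return m[px_ + qx_] * m[py_ + qy_]

    powers = [(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1)]
    G = np.array([[G_entry(px_, py_, qx_, qy_) for (qx_, qy_) in powers] for (px_, py_) in powers])
    G_inv = np.linalg.inv(G)

    # v_k = correlation of image with a(w) * basis_k(w)
    v = np.empty((6,) + f.shape)
    for k, (px_, py_) in enumerate(powers):
        tmp = ndimage.correlate1d(f, kern_x[px_], axis=1, mode="reflect")
        v[k] = ndimage.correlate1d(tmp, kern_x[py_], axis=0, mode="reflect")

    r = np.einsum("ij,j...->i...", G_inv, v)
    return PolyExpansion(
        a11=r[3], a12=r[5] / 2.0, a22=r[4], bx=r[1], by=r[2], c=r[0], sigma_app=sigma_app
    )


def _warp_components(comps: Tuple[np.ndarray, ...], dx: np.ndarray, dy: np.ndarray):
    """Sample each component map at ``(x + dx, y + dy)`` (bilinear, clamped)."""
    h, w = dx.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([(ys + dy).ravel(), (xs + dx).ravel()])
    return [ndimage.map_coordinates(c, coords, order=1, mode="nearest").reshape(h, w) for c in comps]


def _flow_single_scale(
    ref: np.ndarray,
    mov: np.ndarray,
    params: FlowParams,
    dx: np.ndarray,
    dy: np.ndarray,
):
    """Iterative displacement update at one pyramid level."""
    e1 = polynomial_expansion(ref, params.sigma_app)
    e2 = polynomial_expansion(mov, params.sigma_app)
    singular = np.zeros(ref.shape, dtype=bool)
    for _ in range(params.n_iter):
        if np.any(dx) or np.any(dy):
            a11w, a12w, a22w, bxw, byw = _warp_components(
                (e2.a11, e2.a12, e2.a22, e2.bx, e2.by), dx, dy
            )
        else:
            a11w, a12w, a22w, bxw, byw = e2.a11, e2.a12, e2.a22, e2.bx, e2.by
        A11 = 0.5 * (e1.a11 + a11w)
        A12 = 0.5 * (e1.a12 + a12w)
        A22 = 0.5 * (e1.a22 + a22w)
        db_x = -0.5 * (bxw - e1.bx) + A11 * dx + A12 * dy
        db_y = -0.5 * (byw - e1.by) + A12 * dx + A22 * dy

        # aggregate normal equations A^T A d = A^T db over a Gaussian window
        M11 = A11 * A11 + A12 * A12
        M12 = A11 * A12 + A12 * A22
        M22 = A12 * A12 + A22 * A22
        v1 = A11 * db_x + A12 * db_y
        v2 = A12 * db_x + A22 * db_y
        sig = params.agg_window
        M11, M12, M22, v1, v2 = (
            ndimage.gaussian_filter(m, sig, mode="reflect") for m in (M11, M12, M22, v1, v2)
        )
        det = M11 * M22 - M12 * M12
        singular = np.abs(det) < _DET_EPS
        det_safe = np.where(singular, 1.0, det)
        dx_new = (M22 * v1 - M12 * v2) / det_safe
        dy_new = (M11 * v2 - M12 * v1) / det_safe
        dx = np.where(singular, dx, dx_new)
        dy = np.where(singular, dy, dy_new)
    return dx, dy, singular


def estimate_flow(
    ref,
    mov,
    params: Optional[FlowParams] = None,
    prior: Optional[DisplacementField] = None,
) -> DisplacementField:
    """Estimate the dense displacement field mapping ``ref`` onto ``mov``.

    Coarse-to-fine over a Gaussian-ish pyramid, ``n_iter`` refinement passes
    per level.  The returned field's ``valid_mask`` excludes a border of
    ``ceil(3 * sigma_app)`` pixels and any singular pixels.
    """
    params = params or FlowParams()
    f_ref = ref.pixels if isinstance(ref, EnFaceSlab) else np.asarray(ref, dtype=np.float64)
    f_mov = mov.pixels if isinstance(mov, EnFaceSlab) else np.asarray(mov, dtype=np.float64)
    if f_ref.shape != f_mov.shape:
        raise ValueError(f"shape mismatch: {f_ref.shape} vs {f_mov.shape}")

    # pyramid shapes, coarsest last; drop levels that would get too small
    shapes = [f_ref.shape]
    for _ in range(params.pyramid_levels - 1):
        h, w = shapes[-1]
        nh, nw = int(round(h * params.pyramid_scale)), int(round(w * params.pyramid_scale))
        if min(nh, nw) < 24:
            break
        shapes.append((nh, nw))

    def down(img, shape):
        if shape == img.shape:
            return img
        return resize(img, shape, order=1, anti_aliasing=True, mode="reflect")

    h0, w0 = shapes[-1]
    if prior is not None:
        scale = h0 / f_ref.shape[0]
        dx = resize(prior.dx, (h0, w0), order=1, mode="reflect") * scale
        dy = resize(prior.dy, (h0, w0), order=1, mode="reflect") * scale
    else:
        dx = np.zeros((h0, w0))
        dy = np.zeros((h0, w0))

    singular = np.zeros(f_ref.shape, dtype=bool)
    for level in range(len(shapes) - 1, -1, -1):
        shape = shapes[level]
        if dx.shape != shape:
            scale = shape[0] / dx.shape[0]
            dx = resize(dx, shape, order=1, mode="reflect") * scale
            dy = resize(dy, shape, order=1, mode="reflect") * scale
        r, m_ = down(f_ref, shape), down(f_mov, shape)
        dx, dy, singular = _flow_single_scale(r, m_, params, dx, dy)

    border = int(np.ceil(3.0 * params.sigma_app))
    valid = np.zeros(f_ref.shape, dtype=bool)
    valid[border:-border or None, border:-border or None] = True
    valid &= ~singular
    dx = np.where(np.isfinite(dx), dx, 0.0)
    dy = np.where(np.isfinite(dy), dy, 0.0)
    return DisplacementField(dx, dy, valid)


def magnitude(field: DisplacementField, um_per_px: float) -> np.ndarray:
    """Per-pixel displacement magnitude ``sqrt(Dx^2 + Dy^2)`` in micrometers."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    return field.magnitude_px() * um_per_px
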