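"""Dense optical flow by quadratic polynomial expansion.

This is the motion engine behind the contractility analyzer: every local
neighborhood of a grayscale frame is approximated by a quadratic form

    f(x) ~ x^T A x + b^T x + c

with a Gaussian applicability weight, and the displacement field between two
frames is obtained from the translation relation between the two expansions
(Farnebäck's method).  A coarse-to-fine image pyramid handles displacements
larger than the expansion support.  The per-frame scalar readout is |V|, the
mean magnitude of the displacement vectors, which tracks contractile motion
independently of absolute image brightness.

Coordinate convention: ``x`` is the column axis, ``y`` the row axis;
``FlowField.dx``/``dy`` give the displacement (in pixels) of image content
from the earlier to the later frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "FrameStack",
    "FlowParams",
    "PolynomialExpansion",
    "FlowField",
    "MotionTrace",
    "polynomial_expansion",
    "flow_from_expansions",
    "dense_flow",
    "mean_abs_displacement",
    "video_to_trace",
]

# Condition-number cutoff above which the 2x2 normal system is treated as
# singular and the pixel is masked invalid.
_COND_LIMIT = 1e6


@dataclass
class FrameStack:
    """Ordered grayscale frames with a fixed frame interval.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames; any numeric dtype, finite values.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    roi_mask : ndarray of bool, shape (H, W), optional
        Region over which |V| should be averaged.
    """

    frames: np.ndarray
    frame_interval_s: float
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a 3D (time, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ValidationError("a FrameStack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frame intensities must be finite")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be positive")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.frames.shape[1:]:
                raise ValidationError("roi_mask shape must match the frames")
            if not self.roi_mask.any():
                raise ValidationError("roi_mask must select at least one pixel")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FlowParams:
    """Hyperparameters of the pyramidal flow estimator.

    Defaults follow common practice for this algorithm family: 3 pyramid
    levels at scale 0.5, 3 fixed-point iterations per level, expansion
    applicability sigma of 1.5 px and a 15 px Gaussian averaging window.
    """

    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    iterations_per_level: int = 3
    expansion_sigma: float = 1.5
    averaging_window: int = 15

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        if not (0.0 < self.pyramid_scale < 1.0):
            raise ValidationError("pyramid_scale must lie in (0, 1)")
        if self.iterations_per_level < 1:
            raise ValidationError("iterations_per_level must be >= 1")
        if self.expansion_sigma <= 0:
            raise ValidationError("expansion_sigma must be positive")
        if self.averaging_window < 3 or self.averaging_window % 2 == 0:
            raise ValidationError("averaging_window must be odd and >= 3")


@dataclass
class PolynomialExpansion:
    """Per-pixel quadratic model ``f(x) ~ x^T A x + b^T x + c``.

    ``A`` has shape (H, W, 2, 2) and is symmetric at every pixel, ``b`` has
    shape (H, W, 2) ordered (x, y), ``c`` has shape (H, W).
    """

    A: np.ndarray
    b: np.ndarray
    c: np.ndarray
    sigma: float


@dataclass
class FlowField:
    """Displacement field for one frame pair (pixels, earlier -> later)."""

    dx: np.ndarray
    dy: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape:
            raise ValidationError("dx and dy must have identical shapes")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.dx.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.dx.shape:
                raise ValidationError("valid_mask shape must match dx/dy")
        if not np.all(np.isfinite(self.dx[self.valid_mask])) or not np.all(
            np.isfinite(self.dy[self.valid_mask])
        ):
            raise ValidationError("displacements must be finite where valid")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


@dataclass
class MotionTrace:
    """Per-frame mean absolute displacement |V| over time."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValidationError("t and v must be 1D arrays of equal length")
        if np.any(self.v < 0):
            raise ValidationError("|V| values must be non-negative")


def _gaussian_kernel(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    radius = max(3, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return x, g


def polynomial_expansion(frame: np.ndarray, sigma: float) -> PolynomialExpansion:
    """Fit the quadratic model in every Gaussian-weighted neighborhood.

    The fit is solved in closed form through separable correlations with the
    moment kernels {g, x·g, x²·g}; by symmetry of the Gaussian applicability
    the 6x6 normal matrix decouples into a 3x3 block for (c, x², y²) and
    scalars for x, y and xy.  Exact (to round-off) on images that are
    polynomials of degree <= 2, at pixels whose support window lies inside
    the image.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("frame must be a 2D image")
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame must contain only finite values")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    x, g = _gaussian_kernel(sigma)
    support = x.size
    if min(frame.shape) < support:
        raise DegenerateInputError(
            f"image smaller than the {support}-pixel expansion support"
        )

    k0, k1, k2 = g, g * x, g * x**2
    mu0, mu2, mu4 = k0.sum(), (k2).sum(), (g * x**4).sum()

    def corr(img, ky, kx):
        out = ndimage.correlate1d(img, ky, axis=0, mode="nearest")
        return ndimage.correlate1d(out, kx, axis=1, mode="nearest")

    # m[i][j] = sum_w w(y) w(x) y^i x^j f
    row0 = ndimage.correlate1d(frame, k0, axis=0, mode="nearest")
    row1 = ndimage.correlate1d(frame, k1, axis=0, mode="nearest")
    row2 = ndimage.correlate1d(frame, k2, axis=0, mode="nearest")
    m00 = ndimage.correlate1d(row0, k0, axis=1, mode="nearest")
    m01 = ndimage.correlate1d(row0, k1, axis=1, mode="nearest")
    m02 = ndimage.correlate1d(row0, k2, axis=1, mode="nearest")
    m10 = ndimage.correlate1d(row1, k0, axis=1, mode="nearest")
    m11 = ndimage.correlate1d(row1, k1, axis=1, mode="nearest")
    m20 = ndimage.correlate1d(row2, k0, axis=1, mode="nearest")

    b_x = m01 / (mu0 * mu2)
    b_y = m10 / (mu0 * mu2)
    a_xy = 0.5 * m11 / mu2**2

    # coupled (c, x^2, y^2) block
    M = np.array(
        [
            [mu0**2, mu0 * mu2, mu0 * mu2],
            [mu0 * mu2, mu0 * mu4, mu2**2],
            [mu0 * mu2, mu2**2, mu0 * mu4],
        ]
    )
    Minv = np.linalg.inv(M)
    rhs = np.stack([m00, m02, m20], axis=-1)
    sol = rhs @ Minv.T
    c = sol[..., 0]
    a_xx = sol[..., 1]
    a_yy = sol[..., 2]

    H, W = frame.shape
    A = np.empty((H, W, 2, 2))
    A[..., 0, 0] = a_xx
    A[..., 0, 1] = a_xy
    A[..., 1, 0] = a_xy
    A[..., 1, 1] = a_yy
    b = np.stack([b_x, b_y], axis=-1)
    return PolynomialExpansion(A=A, b=b, c=c, sigma=sigma)


def _warp_expansion(e1: PolynomialExpansion, dx, dy):
    """Sample e1's coefficients at x + prior displacement (bilinear)."""
    H, W = e1.c.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    sy = yy + dy
    sx = xx + dx
    inside = (sy >= 0) & (sy <= H - 1) & (sx >= 0) & (sx <= W - 1)
    coords = np.stack([sy, sx])

    def samp(img):
        return ndimage.map_coordinates(img, coords, order=1, mode="nearest")

    A1 = np.empty_like(e1.A)
    A1[..., 0, 0] = samp(e1.A[..., 0, 0])
    A1[..., 0, 1] = samp(e1.A[..., 0, 1])
    A1[..., 1, 1] = samp(e1.A[..., 1, 1])
    A1[..., 1, 0] = A1[..., 0, 1]
    b1 = np.stack([samp(e1.b[..., 0]), samp(e1.b[..., 1])], axis=-1)
    return A1, b1, inside


def flow_from_expansions(
    e0: PolynomialExpansion,
    e1: PolynomialExpansion,
    prior: FlowField | None = None,
    averaging_window: int = 15,
) -> FlowField:
    """One fixed-point displacement update from two polynomial expansions.

    Under a local translation d the expansions satisfy ``A d = Δb`` with
    ``A = (A0 + A1∘warp)/2`` and ``Δb = -(b1∘warp - b0)/2 + A·d_prior``;
    the pointwise constraints are aggregated over a Gaussian averaging
    window and the 2x2 normal system is solved per pixel.  Pixels whose
    normal matrix is near-singular (condition number above 1e6) are masked
    invalid and keep the prior displacement.
    """
    if e0.c.shape != e1.c.shape:
        raise ValidationError("expansions must share the same shape")
    H, W = e0.c.shape
    if prior is None:
        prior = FlowField(np.zeros((H, W)), np.zeros((H, W)))
    if prior.dx.shape != (H, W):
        raise ValidationError("prior shape must match the expansions")
    if not (np.all(np.isfinite(prior.dx)) and np.all(np.isfinite(prior.dy))):
        raise ValidationError("prior must be finite")

    A1, b1, inside = _warp_expansion(e1, prior.dx, prior.dy)
    A = 0.5 * (e0.A + A1)
    a11 = A[..., 0, 0]
    a12 = A[..., 0, 1]
    a22 = A[..., 1, 1]
    db_x = -0.5 * (b1[..., 0] - e0.b[..., 0]) + a11 * prior.dx + a12 * prior.dy
    db_y = -0.5 * (b1[..., 1] - e0.b[..., 1]) + a12 * prior.dx + a22 * prior.dy

    # normal equations G d = h with G = A^T A, h = A^T Δb
    g11 = a11**2 + a12**2
    g12 = a12 * (a11 + a22)
    g22 = a12**2 + a22**2
    h1 = a11 * db_x + a12 * db_y
    h2 = a12 * db_x + a22 * db_y

    cert = inside.astype(float)
    sig = max(1.0, (averaging_window - 1) / 4.0)
    trunc = ((averaging_window - 1) / 2.0) / sig

    def smooth(img):
        return ndimage.gaussian_filter(img * cert, sig, truncate=trunc, mode="nearest")

    G11, G12, G22 = smooth(g11), smooth(g12), smooth(g22)
    H1, H2 = smooth(h1), smooth(h2)

    tr = G11 + G22
    eps = 1e-6 * tr
    G11r = G11 + eps
    G22r = G22 + eps
    det = G11r * G22r - G12**2

    half = 0.5 * (G11r + G22r)
    disc = np.sqrt(np.maximum(0.25 * (G11r - G22r) ** 2 + G12**2, 0.0))
    lam_min = half - disc
    lam_max = half + disc
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lam_min > 0, lam_max / lam_min, np.inf)
    valid = (cond < _COND_LIMIT) & (det > 0) & inside

    with np.errstate(divide="ignore", invalid="ignore"):
        dx = (G22r * H1 - G12 * H2) / det
        dy = (G11r * H2 - G12 * H1) / det
    dx = np.where(valid, dx, prior.dx)
    dy = np.where(valid, dy, prior.dy)
    return FlowField(dx=dx, dy=dy, valid_mask=valid)


def _pyramid(frame: np.ndarray, params: FlowParams) -> list[np.ndarray]:
    levels = [frame]
    support = _gaussian_kernel(params.expansion_sigma)[0].size
    for _ in range(params.pyramid_levels - 1):
        prev = levels[-1]
        shape = (
            max(int(round(prev.shape[0] * params.pyramid_scale)), support),
            max(int(round(prev.shape[1] * params.pyramid_scale)), support),
        )
        if shape == prev.shape:
            break
        levels.append(resize(prev, shape, anti_aliasing=True, mode="reflect"))
    return levels[::-1]  # coarsest first


def dense_flow(f0: np.ndarray, f1: np.ndarray, params: FlowParams | None = None) -> FlowField:
    """Coarse-to-fine displacement field between two frames."""
    params = params or FlowParams()
    f0 = np.asarray(f0, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    if f0.shape != f1.shape:
        raise ValidationError("frames must have identical shapes")
    if f0.ndim != 2:
        raise ValidationError("frames must be 2D grayscale images")

    pyr0 = _pyramid(f0, params)
    pyr1 = _pyramid(f1, params)
    flow = None
    for lvl0, lvl1 in zip(pyr0, pyr1):
        shape = lvl0.shape
        if flow is None:
            flow = FlowField(np.zeros(shape), np.zeros(shape))
        else:
            fy = shape[0] / flow.dx.shape[0]
            fx = shape[1] / flow.dx.shape[1]
            dx = resize(flow.dx, shape, mode="reflect", anti_aliasing=False) * fx
            dy = resize(flow.dy, shape, mode="reflect", anti_aliasing=False) * fy
            flow = FlowField(dx, dy)
        e0 = polynomial_expansion(lvl0, params.expansion_sigma)
        e1 = polynomial_expansion(lvl1, params.expansion_sigma)
        for _ in range(params.iterations_per_level):
            flow = flow_from_expansions(e0, e1, flow, params.averaging_window)
    return flow


def mean_abs_displacement(field: FlowField, roi: np.ndarray | None = None) -> float:
    """Mean |d| over valid (optionally ROI-restricted) pixels: the |V| readout."""
    mask = field.valid_mask
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != field.dx.shape:
            raise ValidationError("roi shape must match the flow field")
        mask = mask & roi
    if not mask.any():
        raise DegenerateInputError("no valid pixels in the requested region")
    return float(np.mean(field.magnitude[mask]))


def video_to_trace(stack: FrameStack, params: FlowParams | None = None) -> MotionTrace:
    """|V| for every consecutive frame pair of a stack.

    Timestamps are assigned to the later frame of each pair, so the trace has
    ``n_frames - 1`` samples starting at one frame interval.
    """
    params = params or FlowParams()
    n = stack.n_frames
    v = np.empty(n - 1)
    for i in range(n - 1):
        field = dense_flow(stack.frames[i], stack.frames[i + 1], params)
        v[i] = mean_abs_displacement(field, stack.roi_mask)
    t = (np.arange(1, n)) * stack.frame_interval_s
    return MotionTrace(t=t, v=v)
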