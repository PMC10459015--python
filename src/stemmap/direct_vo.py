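"""Frame-to-frame egomotion by direct photometric alignment.

The estimator minimizes the sum of squared intensity differences between a
reference frame and a warped input frame over a gradient-selected pixel set,
using the inverse-compositional (IC) formulation: the Jacobian of the warp is
linearized once on the reference frame, each Gauss-Newton step solves for an
incremental warp, and the increment is composed inversely into the running
estimate.  Robustness to non-Gaussian photometric errors (occlusions,
exposure changes, bad disparities) comes from iteratively reweighted least
squares with the Tukey biweight and an MAD residual scale.

The returned twist is the *warp* twist: ``se3_exp(xi)`` maps reference-camera
coordinates of a scene point into input-camera coordinates.  The camera's
physical motion between the frames is its inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import CameraIntrinsics, Twist6, ic_update, se3_exp, warp_pixels
from .stereo import as_disparity, depth_from_disparity

__all__ = [
    "Frame",
    "PixelSelection",
    "ICSystem",
    "RobustConfig",
    "VOResult",
    "DegenerateFrameError",
    "DegenerateTextureError",
    "LowOverlapWarning",
    "to_grayscale",
    "image_gradients",
    "make_frame",
    "select_pixels",
    "build_ic_system",
    "photometric_residuals",
    "robust_weights",
    "estimate_egomotion",
]


class DegenerateFrameError(ValueError):
    """No usable pixels (valid disparity and non-zero gradient) in the frame."""


class DegenerateTextureError(RuntimeError):
    """Weighted Gauss-Newton system is singular."""


class LowOverlapWarning(UserWarning):
    """More than half of the selected pixels warped out of the input frame."""


@dataclass
class Frame:
    """Intensity image bundled with its gradients, disparity and depth."""

    intensity: np.ndarray
    grad_u: np.ndarray
    grad_v: np.ndarray
    disparity: np.ndarray
    depth: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class PixelSelection:
    """Ordered pixel subset with matched depths and gradients."""

    pixels: np.ndarray  # (m, 2) float (u, v)
    depths: np.ndarray  # (m,)
    grads: np.ndarray  # (m, 2) (Iu, Iv)
    intensities: np.ndarray  # (m,) reference intensities

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class ICSystem:
    jacobian: np.ndarray  # (m, 6)
    hessian: np.ndarray  # (6, 6) = J^T J


@dataclass
class RobustConfig:
    """IRLS settings: Tukey constant, MAD consistency factor, stopping rules."""

    c: float = 4.6851
    k: float = 1.4826
    max_iters: int = 100
    step_tol: float = 1e-6
    cost_tol: float = 1e-8
    robust: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0 or self.k <= 0:
            raise ValueError("Tukey constant c and MAD factor k must be positive")


@dataclass
class VOResult:
    xi: Twist6
    iterations: int
    final_cost: float
    converged: bool
    valid_pixel_fraction: float
    cost_trace: list[float] = field(default_factory=list)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Float grayscale in [0, 255]; 3-channel input collapses via luma weights."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return img


def image_gradients(intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients with replicated borders."""
    img = np.asarray(intensity, dtype=float)
    padded = np.pad(img, 1, mode="edge")
    gu = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gv = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return gu, gv


def make_frame(
    intensity: np.ndarray, disparity: np.ndarray, K: CameraIntrinsics
) -> Frame:
    img = to_grayscale(intensity)
    disp = as_disparity(disparity)
    if img.shape != disp.shape:
        raise ValueError(
            f"intensity {img.shape} and disparity {disp.shape} shapes differ"
        )
    gu, gv = image_gradients(img)
    return Frame(img, gu, gv, disp, depth_from_disparity(disp, K))


def select_pixels(frame: Frame, percent: float) -> PixelSelection:
    """Pick the strongest-gradient pixels covering ``percent`` of the image.

    Pixels with zero disparity are discarded first (they back-project to
    infinity), then the remainder are ranked by gradient magnitude in
    descending order with raster-order tie-breaking, and the first
    ``floor(N * percent / 100)`` are kept (N = total pixel count), capped at
    the number of usable pixels.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    h, w = frame.shape
    n_total = h * w
    gmag2 = (frame.grad_u**2 + frame.grad_v**2).ravel()
    usable = (frame.disparity.ravel() > 0) & (gmag2 > 0)
    idx = np.nonzero(usable)[0]
    if idx.size == 0:
        raise DegenerateFrameError("no pixels with valid disparity and gradient")
    order = np.argsort(-gmag2[idx], kind="stable")  # stable: raster tie-break
    target = int(np.floor(n_total * percent / 100.0))
    chosen = idx[order[: min(target, idx.size)]]
    vv, uu = np.unravel_index(chosen, (h, w))
    pixels = np.stack([uu, vv], axis=-1).astype(float)
    return PixelSelection(
        pixels=pixels,
        depths=frame.depth.ravel()[chosen],
        grads=np.stack(
            [frame.grad_u.ravel()[chosen], frame.grad_v.ravel()[chosen]], axis=-1
        ),
        intensities=frame.intensity.ravel()[chosen],
    )


def build_ic_system(
    ref: Frame, sel: PixelSelection, K: CameraIntrinsics
) -> ICSystem:
    """Precompute the IC Jacobian and Gauss-Newton Hessian on the reference.

    Each row is the derivative of the warped reference intensity with respect
    to the six twist parameters at the identity warp, using the back-projected
    point ``x``.  The system depends only on the reference frame, so it is
    computed once and reused for every input frame.
    """
    z = sel.depths
    x = (sel.pixels[:, 0] - K.cu) * z / K.f
    y = (sel.pixels[:, 1] - K.cv) * z / K.f
    X = np.stack([x, y, z], axis=-1)
    gu, gv = sel.grads[:, 0], sel.grads[:, 1]
    # q = gradient row times d(pixel)/d(point): 3-vector per pixel
    q = np.stack(
        [gu * K.f / z, gv * K.f / z, -K.f * (gu * x + gv * y) / z**2], axis=-1
    )
    # rotation block of d(point)/d(twist) at identity is -[x]_x, so the
    # rotation part of each row is q^T(-[x]_x) = x cross q
    J = np.concatenate([np.cross(X, q), q], axis=-1)
    return ICSystem(jacobian=J, hessian=J.T @ J)


def photometric_residuals(
    ref: Frame,
    input_frame: Frame,
    sel: PixelSelection,
    xi: Twist6,
    K: CameraIntrinsics,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals ``I'(W(p; xi)) - I(p)`` with a validity mask.

    Input intensities are sampled with bilinear interpolation at the warped
    sub-pixel positions.  Pixels warping outside the input image or behind
    the camera are masked invalid (residual 0, mask False).
    """
    T = se3_exp(xi)
    coords, in_front = warp_pixels(sel.pixels, T, sel.depths, K)
    h, w = input_frame.shape
    u, v = coords[:, 0], coords[:, 1]
    inside = (
        in_front
        & (u >= 0)
        & (u <= w - 1)
        & (v >= 0)
        & (v <= h - 1)
        & np.isfinite(u)
        & np.isfinite(v)
    )
    sampled = np.zeros(len(sel))
    if np.any(inside):
        sampled[inside] = map_coordinates(
            input_frame.intensity,
            [v[inside], u[inside]],
            order=1,
            mode="nearest",
        )
    residuals = np.where(inside, sampled - sel.intensities, 0.0)
    if np.mean(inside) < 0.5:
        warnings.warn(
            "more than 50% of selected pixels warped out of the input frame",
            LowOverlapWarning,
            stacklevel=2,
        )
    return residuals, inside


def robust_weights(r: np.ndarray, cfg: RobustConfig | None = None) -> np.ndarray:
    """Tukey biweight weights on MAD-standardized residuals.

    Scale ``s = k * median(|r|)``; weight ``(1 - (r/(s c))^2)^2`` inside the
    cutoff ``|r/s| <= c`` and 0 outside.  A zero scale (all residuals tiny)
    yields unit weights.
    """
    cfg = cfg or RobustConfig()
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("residual vector must be non-empty")
    scale = cfg.k * np.median(np.abs(r))
    if scale == 0:
        return np.ones_like(r)
    u = r / scale
    w = np.where(np.abs(u) <= cfg.c, (1.0 - (u / cfg.c) ** 2) ** 2, 0.0)
    return w


def estimate_egomotion(
    ref: Frame,
    input_frame: Frame,
    K: CameraIntrinsics,
    cfg: RobustConfig | None = None,
    percent: float = 25.0,
    xi0: Twist6 | None = None,
    selection: PixelSelection | None = None,
    system: ICSystem | None = None,
) -> VOResult:
    """Estimate the frame-to-frame warp twist by robust IC Gauss-Newton.

    Iterates residual evaluation, Tukey/MAD reweighting, a weighted GN step
    on the precomputed reference-frame system, and the inverse-compositional
    update, until the step norm or the relative cost change is below
    tolerance.  ``xi0`` warm-starts the estimate (default: zero twist, which
    suits small inter-frame motion at video rate).
    """
    cfg = cfg or RobustConfig()
    sel = selection if selection is not None else select_pixels(ref, percent)
    system = system if system is not None else build_ic_system(ref, sel, K)
    J = system.jacobian
    xi = xi0 if xi0 is not None else Twist6.zero()

    prev_cost = np.inf
    cost_trace: list[float] = []
    converged = False
    valid_fraction = 0.0
    iterations = 0
    for iterations in range(1, cfg.max_iters + 1):
        r, valid = photometric_residuals(ref, input_frame, sel, xi, K)
        valid_fraction = float(np.mean(valid))
        if cfg.robust and np.any(valid):
            w = np.zeros_like(r)
            w[valid] = robust_weights(r[valid], cfg)
        else:
            w = valid.astype(float)
        cost = float(np.sum(w * r**2))
        cost_trace.append(cost)

        Jw = J * w[:, None]
        H = J.T @ Jw
        g = Jw.T @ r
        try:
            dxi_arr = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise DegenerateTextureError(
                "weighted Gauss-Newton Hessian is singular"
            ) from exc
        if not np.all(np.isfinite(dxi_arr)):
            raise DegenerateTextureError("non-finite Gauss-Newton step")
        dxi = Twist6.from_array(dxi_arr)
        xi = ic_update(xi, dxi)

        step_norm = float(np.linalg.norm(dxi_arr))
        rel_change = abs(prev_cost - cost) / max(prev_cost, 1e-12)
        if step_norm < cfg.step_tol or rel_change < cfg.cost_tol:
            converged = True
            break
        prev_cost = cost

    return VOResult(
        xi=xi,
        iterations=iterations,
        final_cost=cost_trace[-1] if cost_trace else 0.0,
        converged=converged,
        valid_pixel_fraction=valid_fraction,
        cost_trace=cost_trace,
    )
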