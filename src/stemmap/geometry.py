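"""Lie-group parameterizations, pinhole projection, and pixel warping.

Conventions
-----------
Camera frame: x right, y down, z forward (optical axis).  Image coordinates
``(u, v)`` are column/row, 0-based, origin top-left, with pixel centers at
integer coordinates.  Lengths are meters throughout.

An se(3) twist is ordered rotation-first: ``(omega_x, omega_y, omega_z,
t_x, t_y, t_z)``.  The rotation block of image-alignment Jacobians uses the
sign fixed by finite-difference agreement with :func:`se3_exp` (``-[x]_x``
for the standard exponential), not a printed convention.

The planar (map) frame is a top-down view: a pose is ``(x, y, theta)`` with
``theta`` in (-pi, pi] measured counter-clockwise, and the body x-axis points
along the heading.  :func:`se3_to_se2_motion` maps camera egomotion into this
frame so that chaining planar motions reproduces the plan-view projection of
the chained 3-D camera motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GeometryError",
    "IllConditionedLogError",
    "InvalidDepthError",
    "BehindCameraError",
    "Twist6",
    "RigidTransform3",
    "Pose2",
    "CameraIntrinsics",
    "wrap_angle",
    "rot2",
    "drot2",
    "hat",
    "se3_exp",
    "se3_log",
    "se3_compose",
    "se3_inverse",
    "ic_update",
    "back_project",
    "project",
    "warp_pixel",
    "warp_pixels",
    "se3_to_se2_motion",
    "pose2_compose",
    "pose2_relative",
    "chain_motions",
]

SMALL_ANGLE = 1e-8


class GeometryError(ValueError):
    pass


class IllConditionedLogError(GeometryError):
    """Rotation angle at or near pi: the logarithm map is ill-conditioned."""


class InvalidDepthError(GeometryError):
    pass


class BehindCameraError(GeometryError):
    pass


class Twist6(NamedTuple):
    """se(3) element: rotation part ``omega`` (rad) and translation ``tvec`` (m)."""

    omega: np.ndarray
    tvec: np.ndarray

    @classmethod
    def from_array(cls, xi: np.ndarray) -> "Twist6":
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (6,) or not np.all(np.isfinite(xi)):
            raise GeometryError(f"twist must be a finite 6-vector, got {xi!r}")
        return cls(xi[:3].copy(), xi[3:].copy())

    @classmethod
    def zero(cls) -> "Twist6":
        return cls(np.zeros(3), np.zeros(3))

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.omega, self.tvec])

    def __neg__(self) -> "Twist6":
        return Twist6(-np.asarray(self.omega, float), -np.asarray(self.tvec, float))


@dataclass(frozen=True)
class RigidTransform3:
    """SE(3) element with rotation matrix ``rot`` and translation ``trans``."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rot, dtype=float)
        trans = np.asarray(self.trans, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise GeometryError("RigidTransform3 needs a 3x3 rotation and 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant differs from +1")
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "trans", trans)

    @classmethod
    def identity(cls) -> "RigidTransform3":
        return cls(np.eye(3), np.zeros(3))

    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rot
        T[:3, 3] = self.trans
        return T

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Transform one or many 3-D points (last axis of length 3)."""
        x = np.asarray(x, dtype=float)
        return x @ self.rot.T + self.trans

    def inverse(self) -> "RigidTransform3":
        return RigidTransform3(self.rot.T, -self.rot.T @ self.trans)


class Pose2(NamedTuple):
    """Planar pose / se(2) motion triple (x, y, theta)."""

    x: float
    y: float
    theta: float

    @classmethod
    def from_array(cls, v) -> "Pose2":
        v = np.asarray(v, dtype=float)
        return cls(float(v[0]), float(v[1]), float(wrap_angle(v[2])))


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole model: focal length ``f`` (px), principal point, baseline (m)."""

    f: float
    cu: float
    cv: float
    baseline: float
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise GeometryError("focal length must be positive")
        if self.baseline <= 0:
            raise GeometryError("stereo baseline must be positive")

    def matrix(self) -> np.ndarray:
        return np.array([[self.f, 0, self.cu], [0, self.f, self.cv], [0, 0, 1.0]])

    def inverse_matrix(self) -> np.ndarray:
        f, cu, cv = self.f, self.cu, self.cv
        return np.array([[1 / f, 0, -cu / f], [0, 1 / f, -cv / f], [0, 0, 1.0]])


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = np.remainder(a + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.ndim else float(out)


def rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def drot2(theta: float) -> np.ndarray:
    """Derivative of :func:`rot2` with respect to the angle."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[-s, -c], [c, -s]])


def hat(w: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix such that ``hat(w) @ v == cross(w, v)``."""
    w = np.asarray(w, dtype=float)
    return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])


def _vee(M: np.ndarray) -> np.ndarray:
    return np.array([M[2, 1], M[0, 2], M[1, 0]])


def se3_exp(xi: Twist6) -> RigidTransform3:
    """Closed-form exponential map se(3) -> SE(3) (Rodrigues + V-matrix)."""
    if not isinstance(xi, Twist6):
        xi = Twist6.from_array(np.asarray(xi))
    w = np.asarray(xi.omega, dtype=float)
    t = np.asarray(xi.tvec, dtype=float)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(t))):
        raise GeometryError("twist entries must be finite")
    theta = float(np.linalg.norm(w))
    W = hat(w)
    W2 = W @ W
    if theta < SMALL_ANGLE:
        R = np.eye(3) + W + 0.5 * W2
        V = np.eye(3) + 0.5 * W + W2 / 6.0
    else:
        A = np.sin(theta) / theta
        # 1 - cos(theta) via 2 sin^2(theta/2): stable for small angles
        B = 2.0 * np.sin(theta / 2.0) ** 2 / theta**2
        C = (1.0 - A) / theta**2
        R = np.eye(3) + A * W + B * W2
        V = np.eye(3) + B * W + C * W2
    # Re-orthonormalize to keep the RigidTransform3 invariant tight.
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    return RigidTransform3(R, V @ t)


def se3_log(T: RigidTransform3) -> Twist6:
    """Logarithm map SE(3) -> se(3); requires rotation angle < pi."""
    R, t = np.asarray(T.rot, float), np.asarray(T.trans, float)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta > np.pi - 1e-6:
        raise IllConditionedLogError(
            f"rotation angle {theta:.6f} rad is too close to pi"
        )
    if theta < SMALL_ANGLE:
        w = _vee(R - R.T) / 2.0
        Vinv = np.eye(3) - 0.5 * hat(w) + hat(w) @ hat(w) / 12.0
    else:
        w = theta / (2.0 * np.sin(theta)) * _vee(R - R.T)
        W = hat(w)
        coeff = (1.0 / theta**2) - (1.0 + np.cos(theta)) / (
            2.0 * theta * np.sin(theta)
        )
        Vinv = np.eye(3) - 0.5 * W + coeff * (W @ W)
    return Twist6(w, Vinv @ t)


def se3_compose(a: RigidTransform3, b: RigidTransform3) -> RigidTransform3:
    return RigidTransform3(a.rot @ b.rot, a.rot @ b.trans + a.trans)


def se3_inverse(T: RigidTransform3) -> RigidTransform3:
    return T.inverse()


def ic_update(xi: Twist6, dxi: Twist6) -> Twist6:
    """Inverse-compositional parameter update: ``log(exp(xi) exp(-dxi))``."""
    return se3_log(se3_compose(se3_exp(xi), se3_exp(-dxi)))


def back_project(p: np.ndarray, z, K: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel(s) ``p`` at depth(s) ``z`` to homogenized 4-vectors."""
    single = np.asarray(p).ndim == 1
    p = np.atleast_2d(np.asarray(p, dtype=float))
    z = np.broadcast_to(np.asarray(z, dtype=float), p.shape[:1]).astype(float)
    if np.any(z <= 0):
        raise InvalidDepthError("back-projection requires depth > 0")
    x = (p[:, 0] - K.cu) * z / K.f
    y = (p[:, 1] - K.cv) * z / K.f
    out = np.stack([x, y, z, np.ones_like(z)], axis=-1)
    return out[0] if single else out


def project(x: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of 3-D point(s) with homogeneous normalization."""
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))[:, :3]
    if np.any(x[:, 2] <= 0):
        raise InvalidDepthError("projection requires points with z > 0")
    u = K.f * x[:, 0] / x[:, 2] + K.cu
    v = K.f * x[:, 1] / x[:, 2] + K.cv
    out = np.stack([u, v], axis=-1)
    return out[0] if single else out


def warp_pixel(p, xi: Twist6, z: float, K: CameraIntrinsics) -> np.ndarray:
    """Warp one pixel: project(T(xi) backproject(p, z)).

    Raises :class:`BehindCameraError` if the transformed point has
    non-positive depth.  The result may lie outside the image domain;
    bounds handling is the caller's concern.
    """
    X = back_project(np.asarray(p, float).reshape(1, 2), z, K)[:, :3]
    T = se3_exp(xi)
    Xw = T.apply(X)
    if Xw[0, 2] <= 0:
        raise BehindCameraError("warped point falls behind the camera")
    return project(Xw, K)


def warp_pixels(
    p: np.ndarray, T: RigidTransform3, z: np.ndarray, K: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized warp of many pixels; returns (coords, in-front mask).

    Pixels whose transformed depth is non-positive get NaN coordinates and a
    False mask entry instead of raising.
    """
    p = np.asarray(p, dtype=float)
    z = np.asarray(z, dtype=float)
    X = np.stack(
        [(p[:, 0] - K.cu) * z / K.f, (p[:, 1] - K.cv) * z / K.f, z], axis=-1
    )
    Xw = X @ T.rot.T + T.trans
    ok = Xw[:, 2] > 0
    out = np.full_like(p, np.nan)
    zw = np.where(ok, Xw[:, 2], 1.0)
    out[:, 0] = np.where(ok, K.f * Xw[:, 0] / zw + K.cu, np.nan)
    out[:, 1] = np.where(ok, K.f * Xw[:, 1] / zw + K.cv, np.nan)
    return out, ok


def se3_to_se2_motion(xi: Twist6) -> Pose2:
    """Project a camera-frame se(3) motion onto the planar map frame.

    The planar triple is ``(t_x, t_z, -theta_y)``: translation along the
    camera x (lateral) and z (forward) axes, and the heading change about the
    vertical.  The heading sign is chosen so that composing planar motions
    with :func:`pose2_compose` reproduces the plan-view projection of the
    composed 3-D motions (the camera y-axis points down, so a positive
    rotation about it is a clockwise turn seen from above).
    """
    if not isinstance(xi, Twist6):
        xi = Twist6.from_array(np.asarray(xi))
    T = se3_exp(xi)
    theta = float(np.arctan2(-T.rot[0, 2], T.rot[2, 2]))
    return Pose2(float(T.trans[0]), float(T.trans[2]), theta)


def pose2_compose(pose, motion) -> np.ndarray:
    """Advance a planar pose by a body-frame motion triple."""
    pose = np.asarray(pose, dtype=float)
    motion = np.asarray(motion, dtype=float)
    t = pose[:2] + rot2(pose[2]) @ motion[:2]
    return np.array([t[0], t[1], wrap_angle(pose[2] + motion[2])])


def pose2_relative(pose_i, pose_j) -> np.ndarray:
    """Body-frame motion taking ``pose_i`` to ``pose_j`` (inverse of compose)."""
    pose_i = np.asarray(pose_i, dtype=float)
    pose_j = np.asarray(pose_j, dtype=float)
    dt = rot2(pose_i[2]).T @ (pose_j[:2] - pose_i[:2])
    return np.array([dt[0], dt[1], wrap_angle(pose_j[2] - pose_i[2])])


def chain_motions(motions: np.ndarray, start=None) -> np.ndarray:
    """Chain body-frame motion triples into a pose array of shape (n+1, 3)."""
    motions = np.atleast_2d(np.asarray(motions, dtype=float))
    pose = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    out = np.empty((len(motions) + 1, 3))
    out[0] = pose
    for i, m in enumerate(motions):
        pose = pose2_compose(pose, m)
        out[i + 1] = pose
    return out
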