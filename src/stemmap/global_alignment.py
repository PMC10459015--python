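"""Planar pose-graph fusion of odometry with GPS/UTM positions.

The graph has one node per camera pose (x, y, theta), consecutive-pose motion
edges from odometry with 3x3 information matrices, GPS position constraints
with 2x2 information matrices, and a single global-orientation parameter phi
that rotates the odometry frame into the UTM frame.  The state

    s = (phi, v1, ..., vn)

is optimized by Levenberg-Marquardt on the weighted sum of squared motion and
position residuals, with the sparse normal equations assembled analytically
and solved by a sparse factorization.  GPS residuals can be reweighted each
iteration with the Tukey biweight on MAD-standardized residual norms, which
scales the per-fix information matrix and suppresses outlier fixes.

The GPS track is anchored by subtracting the first corresponded coordinate
before optimization; :func:`recover_global` undoes the anchoring and applies
the converged global orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Pose2, pose2_compose, rot2, drot2, wrap_angle

__all__ = [
    "OdometryEdge",
    "GpsObservation",
    "GlobalState",
    "LMConfig",
    "GraphError",
    "UnresolvableOrientationError",
    "default_odometry_info",
    "default_gps_info",
    "build_graph",
    "anchor_gps",
    "odometry_error",
    "gps_error",
    "gps_robust_weights",
    "assemble_normal_equations",
    "lm_optimize",
    "recover_global",
    "correspond_by_timestamp",
]


class GraphError(ValueError):
    pass


class UnresolvableOrientationError(GraphError):
    """Fewer than two GPS observations: phi cannot be resolved."""


@dataclass(frozen=True)
class OdometryEdge:
    """Motion constraint between consecutive poses i and i+1."""

    i: int
    motion: np.ndarray  # (3,) dx, dy (m), dtheta (rad) in the body frame of i
    info: np.ndarray  # (3, 3) SPD information matrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "motion", np.asarray(self.motion, dtype=float))
        info = np.asarray(self.info, dtype=float)
        _check_spd(info, "odometry information")
        object.__setattr__(self, "info", info)


@dataclass(frozen=True)
class GpsObservation:
    """A UTM position fix tied to one camera pose."""

    coord: np.ndarray  # (2,) easting, northing (m)
    info: np.ndarray  # (2, 2) SPD information matrix
    pose_index: int
    pdop: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        info = np.asarray(self.info, dtype=float)
        _check_spd(info, "GPS information")
        object.__setattr__(self, "info", info)


@dataclass
class GlobalState:
    """Optimization state: global orientation, poses, and the stored anchor."""

    phi: float
    poses: np.ndarray  # (n, 3)
    anchor: np.ndarray  # (2,) g0 in UTM meters

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.phi], self.poses.ravel()])

    @classmethod
    def from_vector(cls, x: np.ndarray, anchor: np.ndarray) -> "GlobalState":
        x = np.asarray(x, dtype=float)
        poses = x[1:].reshape(-1, 3).copy()
        poses[:, 2] = wrap_angle(poses[:, 2])
        return cls(phi=float(x[0]), poses=poses, anchor=np.asarray(anchor, float))


@dataclass
class LMConfig:
    """Levenberg-Marquardt schedule and robustness switches."""

    step_tol: float = 1e-3
    max_iters: int = 100
    # "diag_scaled" (tau * max diag), "trace", "trace/n", or a fixed value
    # via lambda_init.  With stiff odometry information the trace-based
    # inits exceed the per-block curvature by orders of magnitude and the
    # first damped step falls below step_tol before the solver moves, so the
    # default starts essentially at Gauss-Newton and lets step rejection
    # grow the damping when needed.
    lambda_init_rule: str = "diag_scaled"
    lambda_tau: float = 1e-8
    lambda_init: float | None = None
    lambda_up: float = 2.0
    lambda_down: float = 0.5
    robust_gps: bool = False
    tukey_c: float = 4.6851
    mad_k: float = 1.4826
    phi_grid_init: bool = True
    max_rejects: int = 60
    dense_threshold: int = 200

    def __post_init__(self) -> None:
        if self.lambda_up <= 0 or self.lambda_down <= 0:
            raise ValueError("lambda factors must be positive")


def _check_spd(M: np.ndarray, name: str) -> None:
    if M.shape not in ((2, 2), (3, 3)):
        raise GraphError(f"{name} matrix has wrong shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-9):
        raise GraphError(f"{name} matrix must be symmetric")
    if np.any(np.linalg.eigvalsh(M) <= 0):
        raise GraphError(f"{name} matrix must be positive definite")


def default_odometry_info(
    sigma_t: float = 0.1, sigma_theta: float = 0.005
) -> np.ndarray:
    """Diagonal motion information; heading much stiffer than translation."""
    return np.diag([1 / sigma_t**2, 1 / sigma_t**2, 1 / sigma_theta**2])


def default_gps_info(
    sigma: float = 5.0, pdop: float | None = None, use_pdop: bool = False
) -> np.ndarray:
    """Isotropic position information; PDOP optionally scales sigma per fix."""
    s = sigma * (pdop if (use_pdop and pdop is not None and pdop > 0) else 1.0)
    s = max(s, 1e-6)
    return np.eye(2) / s**2


def build_graph(edges: Sequence[OdometryEdge]) -> np.ndarray:
    """Chain odometry edges into an initial pose array, first pose at zero."""
    for k, e in enumerate(edges):
        if e.i != k:
            raise GraphError("edges must connect consecutive poses 0,1,2,...")
    poses = np.zeros((len(edges) + 1, 3))
    for k, e in enumerate(edges):
        poses[k + 1] = pose2_compose(poses[k], e.motion)
    return poses


def anchor_gps(
    gps: Sequence[GpsObservation],
) -> tuple[list[GpsObservation], np.ndarray]:
    """Translate the track so the first corresponded fix is the origin.

    Returns the anchored observations and the stored offset g0 (needed by
    :func:`recover_global` to restore UTM coordinates).  At least two fixes
    are required for the global orientation to be observable.
    """
    if len(gps) < 2:
        raise UnresolvableOrientationError(
            "at least two GPS observations are required"
        )
    g0 = np.asarray(gps[0].coord, dtype=float).copy()
    return [replace(g, coord=g.coord - g0) for g in gps], g0


def odometry_error(vi, vj, motion) -> np.ndarray:
    """Motion residual: vj expressed in vi's frame, compared to the edge.

    Defined through the transform product T(motion)^-1 T(vi)^-1 T(vj); zero
    exactly when vj is the composition of vi with the edge motion.  The angle
    component is wrapped to (-pi, pi].
    """
    vi = np.asarray(vi, dtype=float)
    vj = np.asarray(vj, dtype=float)
    motion = np.asarray(motion, dtype=float)
    r_t = rot2(motion[2]).T @ (rot2(vi[2]).T @ (vj[:2] - vi[:2]) - motion[:2])
    return np.array([r_t[0], r_t[1], wrap_angle(vj[2] - vi[2] - motion[2])])


def gps_error(vi, phi: float, g) -> np.ndarray:
    """Position residual: pose translation rotated by phi minus the fix."""
    vi = np.asarray(vi, dtype=float)
    return rot2(phi) @ vi[:2] - np.asarray(g, dtype=float)


def gps_robust_weights(
    state: GlobalState,
    gps: Sequence[GpsObservation],
    c: float = 4.6851,
    k: float = 1.4826,
) -> np.ndarray:
    """Tukey biweight per fix on MAD-standardized GPS residual norms."""
    norms = np.array(
        [
            np.linalg.norm(gps_error(state.poses[g.pose_index], state.phi, g.coord))
            for g in gps
        ]
    )
    scale = k * np.median(norms)
    if scale == 0:
        return np.ones(len(gps))
    u = norms / scale
    return np.where(u <= c, (1.0 - (u / c) ** 2) ** 2, 0.0)


def _odometry_terms(poses: np.ndarray, edges: Sequence[OdometryEdge]):
    """Vectorized residuals and A/B Jacobian blocks for all edges."""
    m = len(edges)
    i_idx = np.arange(m)
    motions = np.stack([e.motion for e in edges])
    Q = np.stack([e.info for e in edges])
    ti = poses[i_idx, :2]
    tj = poses[i_idx + 1, :2]
    thi = poses[i_idx, 2]
    thj = poses[i_idx + 1, 2]
    thij = motions[:, 2]

    def rots(a):
        c, s = np.cos(a), np.sin(a)
        return np.stack(
            [np.stack([c, -s], -1), np.stack([s, c], -1)], axis=-2
        )  # (m,2,2)

    Ri = rots(thi)
    Rij = rots(thij)
    dRiT = np.transpose(rots(thi + np.pi / 2), (0, 2, 1))  # d(R^T)/dtheta
    dt = tj - ti
    RiT_dt = np.einsum("mji,mj->mi", Ri, dt)
    r_t = np.einsum("mji,mj->mi", Rij, RiT_dt - motions[:, :2])
    r = np.concatenate(
        [r_t, wrap_angle(thj - thi - thij)[:, None]], axis=1
    )  # (m,3)

    RijT_RiT = np.einsum("mji,mkj->mik", Rij, Ri)  # Rij^T Ri^T
    A = np.zeros((m, 3, 3))
    A[:, :2, :2] = -RijT_RiT
    A[:, :2, 2] = np.einsum("mji,mjk,mk->mi", Rij, dRiT, dt)
    A[:, 2, 2] = -1.0
    B = np.zeros((m, 3, 3))
    B[:, :2, :2] = RijT_RiT
    B[:, 2, 2] = 1.0
    return r, A, B, Q


def _gps_terms(
    poses: np.ndarray, phi: float, gps: Sequence[GpsObservation], weights
):
    g = len(gps)
    idx = np.array([o.pose_index for o in gps])
    coords = np.stack([o.coord for o in gps])
    Q = np.stack([o.info for o in gps])
    if weights is not None:
        Q = Q * np.asarray(weights, dtype=float)[:, None, None]
    ti = poses[idx, :2]
    R = rot2(phi)
    dR = drot2(phi)
    r = ti @ R.T - coords  # (g,2)
    C = ti @ dR.T  # (g,2) column for phi
    D = np.broadcast_to(R, (g, 2, 2))  # translation block of each pose
    return r, C, D, Q, idx


def assemble_normal_equations(
    state: GlobalState,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    weights: np.ndarray | None = None,
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sparse Gauss-Newton system (H, b) at the current linearization point.

    H is (1+3n) x (1+3n) with the phi row/column first; ``weights`` scales
    the per-fix GPS information (robust IRLS).  The gradient b is
    sum(J^T Q r), so the LM step solves (H + lambda I) ds = -b.
    """
    n = len(state.poses)
    dim = 1 + 3 * n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(dim)

    if len(edges) > 0:
        r, A, B, Q = _odometry_terms(state.poses, edges)
        m = len(edges)
        Je = np.concatenate([A, B], axis=2)  # (m,3,6)
        QJ = np.einsum("mij,mjk->mik", Q, Je)
        Hblk = np.einsum("mji,mjk->mik", Je, QJ)  # (m,6,6)
        bblk = np.einsum("mji,mjk,mk->mi", Je, Q, r)  # (m,6)
        offs = 1 + 3 * np.arange(m)
        block_cols = offs[:, None] + np.arange(6)[None, :]  # (m,6)
        rows.append(np.repeat(block_cols, 6, axis=1).ravel())
        cols.append(np.tile(block_cols, (1, 6)).ravel())
        vals.append(Hblk.ravel())
        np.add.at(b, block_cols.ravel(), bblk.ravel())

    if len(gps) > 0:
        r, C, D, Q, idx = _gps_terms(state.poses, state.phi, gps, weights)
        g = len(gps)
        # stacked Jacobian [C | D | 0] per fix: columns (phi, x_i, y_i, theta_i)
        Jg = np.zeros((g, 2, 4))
        Jg[:, :, 0] = C
        Jg[:, :, 1:3] = D
        QJ = np.einsum("gij,gjk->gik", Q, Jg)
        Hblk = np.einsum("gji,gjk->gik", Jg, QJ)  # (g,4,4)
        bblk = np.einsum("gji,gjk,gk->gi", Jg, Q, r)  # (g,4)
        offs = 1 + 3 * idx
        block_cols = np.concatenate(
            [np.zeros((g, 1), dtype=int), offs[:, None] + np.arange(3)[None, :]],
            axis=1,
        )  # (g,4)
        rows.append(np.repeat(block_cols, 4, axis=1).ravel())
        cols.append(np.tile(block_cols, (1, 4)).ravel())
        vals.append(Hblk.ravel())
        np.add.at(b, block_cols.ravel(), bblk.ravel())

    if not vals:
        return sp.csc_matrix((dim, dim)), b
    H = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    ).tocsc()
    return H, b


def _objective(
    state: GlobalState,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    weights: np.ndarray | None,
) -> float:
    total = 0.0
    if len(edges) > 0:
        r, _, _, Q = _odometry_terms(state.poses, edges)
        total += float(np.einsum("mi,mij,mj->", r, Q, r))
    if len(gps) > 0:
        r, _, _, Q, _ = _gps_terms(state.poses, state.phi, gps, weights)
        total += float(np.einsum("gi,gij,gj->", r, Q, r))
    return total


def _solve_damped(H, b, lam: float, dense: bool) -> np.ndarray:
    dim = H.shape[0]
    if dense:
        Hd = H.toarray() if sp.issparse(H) else np.asarray(H)
        return np.linalg.solve(Hd + lam * np.eye(dim), -b)
    Hl = (H + lam * sp.identity(dim, format="csc")).tocsc()
    try:
        lu = spla.splu(Hl)
        return lu.solve(-b)
    except RuntimeError as exc:  # singular factorization
        raise GraphError("damped normal equations are singular") from exc


def lm_minimize(
    x0: np.ndarray,
    build: Callable[[np.ndarray], tuple],
    cfg: LMConfig,
) -> tuple[np.ndarray, dict]:
    """Generic damped Gauss-Newton driver shared by alignment and refinement.

    ``build(x)`` returns ``(H, b, obj, eval_obj)`` where ``obj`` is the
    objective at ``x`` and ``eval_obj(x')`` evaluates it elsewhere with the
    same (frozen) robust weights.  Steps that increase the objective are
    rejected with the damping doubled; accepted steps halve it.  Terminates
    when the accepted step norm drops below ``cfg.step_tol``.
    """
    x = np.asarray(x0, dtype=float).copy()
    dense = x.size < cfg.dense_threshold
    lam = cfg.lambda_init
    history = {"objective": [], "lambda": [], "step_norm": []}
    for _ in range(cfg.max_iters):
        H, b, obj, eval_obj = build(x)
        if lam is None:
            if cfg.lambda_init_rule == "trace":
                lam = float(H.diagonal().sum())
            elif cfg.lambda_init_rule == "trace/n":
                lam = float(H.diagonal().sum()) / H.shape[0]
            elif cfg.lambda_init_rule == "diag_scaled":
                lam = cfg.lambda_tau * float(H.diagonal().max())
            else:
                lam = 1.0
        accepted = False
        for _reject in range(cfg.max_rejects):
            ds = _solve_damped(H, b, lam, dense)
            if not np.all(np.isfinite(ds)):
                raise GraphError("non-finite LM step")
            x_new = x + ds
            obj_new = eval_obj(x_new)
            if obj_new <= obj:
                lam *= cfg.lambda_down
                accepted = True
                break
            lam *= cfg.lambda_up
        if not accepted:
            break
        x = x_new
        step = float(np.linalg.norm(ds))
        history["objective"].append(obj_new)
        history["lambda"].append(lam)
        history["step_norm"].append(step)
        if step < cfg.step_tol:
            break
    return x, history


def _grid_init_phi(
    state: GlobalState, gps: Sequence[GpsObservation], n_angles: int = 16
) -> float:
    """Coarse phi initialization: median GPS misfit over a rotation grid."""
    idx = np.array([g.pose_index for g in gps])
    coords = np.stack([g.coord for g in gps])
    ti = state.poses[idx, :2]
    best_phi, best_cost = 0.0, np.inf
    for phi in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        resid = ti @ rot2(phi).T - coords
        cost = float(np.median(np.sum(resid**2, axis=1)))
        if cost < best_cost:
            best_phi, best_cost = phi, cost
    return float(wrap_angle(best_phi))


def lm_optimize(
    state: GlobalState,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    cfg: LMConfig | None = None,
) -> tuple[GlobalState, dict]:
    """Optimize (phi, poses) against odometry and anchored GPS constraints.

    Expects anchored GPS (see :func:`anchor_gps`).  Returns the optimized
    state and a history dict with per-iteration objective, damping, and step
    norm.  With ``cfg.robust_gps`` the per-fix information is scaled each
    iteration by Tukey weights on MAD-standardized residual norms.
    """
    cfg = cfg or LMConfig()
    if len(gps) < 2:
        raise UnresolvableOrientationError(
            "at least two GPS observations are required"
        )
    anchor = state.anchor
    if cfg.phi_grid_init:
        state = replace(state, phi=_grid_init_phi(state, gps))

    def build(x: np.ndarray):
        st = GlobalState.from_vector(x, anchor)
        weights = (
            gps_robust_weights(st, gps, cfg.tukey_c, cfg.mad_k)
            if cfg.robust_gps
            else None
        )
        H, b = assemble_normal_equations(st, edges, gps, weights)
        obj = _objective(st, edges, gps, weights)

        def eval_obj(x_new: np.ndarray) -> float:
            return _objective(
                GlobalState.from_vector(x_new, anchor), edges, gps, weights
            )

        return H, b, obj, eval_obj

    x_opt, history = lm_minimize(state.as_vector(), build, cfg)
    return GlobalState.from_vector(x_opt, anchor), history


def recover_global(state: GlobalState) -> np.ndarray:
    """Rotate poses by the converged phi and restore UTM coordinates.

    Returns an (n, 3) pose array; phi is consumed here and dropped from any
    further processing.
    """
    R = rot2(state.phi)
    out = np.empty_like(state.poses)
    out[:, :2] = state.poses[:, :2] @ R.T + state.anchor
    out[:, 2] = wrap_angle(state.poses[:, 2] + state.phi)
    return out


def correspond_by_timestamp(
    frame_times: np.ndarray, gps_times: np.ndarray, window_s: float = 0.5
) -> list[tuple[int, int]]:
    """Match GPS fixes to frames: identity when counts agree, else nearest
    timestamp within ``window_s`` seconds."""
    frame_times = np.asarray(frame_times, dtype=float)
    gps_times = np.asarray(gps_times, dtype=float)
    if len(frame_times) == len(gps_times):
        return [(i, i) for i in range(len(frame_times))]
    pairs = []
    for k, t in enumerate(gps_times):
        i = int(np.argmin(np.abs(frame_times - t)))
        if abs(frame_times[i] - t) <= window_s:
            pairs.append((i, k))
    return pairs
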