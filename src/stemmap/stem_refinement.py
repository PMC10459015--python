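"""Stem landmark association and joint pose/landmark refinement.

Per-frame stem detections (camera-frame offsets) are transformed into the
world frame with the globally aligned poses, associated into landmarks by
density-based clustering (DBSCAN, Euclidean metric, label 0 = outlier), and
initialized at the cluster means.  The augmented state

    s = (v1, ..., vn, m1, ..., mL)

is then optimized by the same damped Gauss-Newton scheme as global
alignment, over the odometry, GPS, and stem-observation residuals.  The
global orientation parameter is consumed before refinement, so the GPS
translation block reduces to the identity.

Clustering runs once, before optimization; associations are not revisited
between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import DBSCAN

from .geometry import rot2, wrap_angle
from .global_alignment import (
    GpsObservation,
    LMConfig,
    OdometryEdge,
    _odometry_terms,
    lm_minimize,
)

__all__ = [
    "StemObservation",
    "ClusterAssignment",
    "StemMap",
    "AugmentedState",
    "EmptyMapError",
    "default_stem_info",
    "observation_sigma",
    "observations_to_world",
    "dbscan_cluster",
    "cluster_centers",
    "stem_error",
    "assemble_refinement_system",
    "refine_map",
    "RefinementResult",
]


class EmptyMapError(RuntimeError):
    """Clustering produced no landmark clusters."""


@dataclass(frozen=True)
class StemObservation:
    """One stem detection: camera-frame planar offset with information.

    ``offset[0]`` is the forward (along-heading) component, which must be
    positive (the stem is in front of the camera); ``offset[1]`` is the
    lateral (left-positive) component.
    """

    pose_index: int
    obs_index: int
    offset: np.ndarray  # (2,) forward, lateral (m)
    info: np.ndarray  # (2, 2) SPD

    def __post_init__(self) -> None:
        off = np.asarray(self.offset, dtype=float)
        if off[0] <= 0:
            raise ValueError("stem observation must lie in front of the camera")
        object.__setattr__(self, "offset", off)
        object.__setattr__(self, "info", np.asarray(self.info, dtype=float))


@dataclass
class ClusterAssignment:
    """Per-observation labels; 0 marks an outlier, clusters are 1..n_labels."""

    labels: np.ndarray

    @property
    def label_set(self) -> np.ndarray:
        labels = np.unique(self.labels)
        return labels[labels > 0]

    @property
    def n_clusters(self) -> int:
        return len(self.label_set)


@dataclass
class StemMap:
    """Estimated stem positions with per-cluster support and spread."""

    centers: np.ndarray  # (L, 2) UTM meters
    counts: np.ndarray  # (L,) observations per cluster
    covariances: np.ndarray  # (L, 2, 2) empirical


@dataclass
class AugmentedState:
    poses: np.ndarray  # (n, 3)
    centers: np.ndarray  # (L, 2)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.poses.ravel(), self.centers.ravel()])

    @classmethod
    def from_vector(cls, x: np.ndarray, n_poses: int) -> "AugmentedState":
        x = np.asarray(x, dtype=float)
        poses = x[: 3 * n_poses].reshape(-1, 3).copy()
        poses[:, 2] = wrap_angle(poses[:, 2])
        return cls(poses=poses, centers=x[3 * n_poses :].reshape(-1, 2).copy())


def observation_sigma(distance: float | np.ndarray) -> np.ndarray:
    """Range-dependent detection noise model: sigma = 0.1 + 0.05 d (m)."""
    return 0.1 + 0.05 * np.asarray(distance, dtype=float)


def default_stem_info(distance: float) -> np.ndarray:
    """Isotropic observation information from the range-dependent sigma."""
    s = float(observation_sigma(distance))
    return np.eye(2) / s**2


def observations_to_world(
    obs: Sequence[StemObservation], poses: np.ndarray
) -> np.ndarray:
    """Rotate/translate camera-frame offsets into the world frame."""
    poses = np.asarray(poses, dtype=float)
    idx = np.array([o.pose_index for o in obs], dtype=int)
    if len(obs) and (idx.min() < 0 or idx.max() >= len(poses)):
        raise IndexError("observation pose index out of range")
    z = np.stack([o.offset for o in obs]) if obs else np.zeros((0, 2))
    th = poses[idx, 2]
    c, s = np.cos(th), np.sin(th)
    world = np.empty_like(z)
    world[:, 0] = c * z[:, 0] - s * z[:, 1]
    world[:, 1] = s * z[:, 0] + c * z[:, 1]
    return world + poses[idx, :2]


def dbscan_cluster(
    points: np.ndarray, radius: float = 1.0, min_pts: int = 10
) -> ClusterAssignment:
    """Density-based association of world points into stem clusters.

    Euclidean metric; defaults are a 1 m search radius and 10 minimum points.
    Deterministic for a fixed point order.  Noise points get label 0 and
    clusters are numbered from 1 in order of first appearance.
    """
    if radius <= 0 or min_pts < 1:
        raise ValueError("radius must be > 0 and min_pts >= 1")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return ClusterAssignment(labels=np.zeros(0, dtype=int))
    raw = DBSCAN(eps=radius, min_samples=min_pts).fit(points).labels_
    return ClusterAssignment(labels=(raw + 1).astype(int))


def cluster_centers(
    points: np.ndarray, assignment: ClusterAssignment
) -> StemMap:
    """Per-cluster arithmetic means with empirical covariances.

    Outliers (label 0) are excluded from every mean.  Raises
    :class:`EmptyMapError` when no cluster exists.
    """
    points = np.asarray(points, dtype=float)
    labels = assignment.label_set
    if len(labels) == 0:
        raise EmptyMapError("no stem clusters found")
    centers = np.empty((len(labels), 2))
    counts = np.empty(len(labels), dtype=int)
    covs = np.empty((len(labels), 2, 2))
    for k, lab in enumerate(labels):
        member = points[assignment.labels == lab]
        centers[k] = member.mean(axis=0)
        counts[k] = len(member)
        covs[k] = np.cov(member, rowvar=False, ddof=1)
    return StemMap(centers=centers, counts=counts, covariances=covs)


def stem_error(pose, center, obs: StemObservation | np.ndarray) -> np.ndarray:
    """Landmark residual: center mapped into the camera frame, minus the
    observation.  Exact inverse of :func:`observations_to_world`."""
    pose = np.asarray(pose, dtype=float)
    z = obs.offset if isinstance(obs, StemObservation) else np.asarray(obs, float)
    return rot2(pose[2]).T @ (np.asarray(center, float) - pose[:2]) - z


def _stem_terms(
    aug: AugmentedState,
    obs: Sequence[StemObservation],
    assignment: ClusterAssignment,
):
    """Vectorized residuals and E/F blocks for all clustered observations."""
    mask = assignment.labels > 0
    sel = [o for o, m in zip(obs, mask) if m]
    pidx = np.array([o.pose_index for o in sel], dtype=int)
    lidx = assignment.labels[mask] - 1
    z = np.stack([o.offset for o in sel])
    Q = np.stack([o.info for o in sel])
    th = aug.poses[pidx, 2]
    t = aug.poses[pidx, :2]
    d = aug.centers[lidx] - t
    c, s = np.cos(th), np.sin(th)
    RT = np.stack(
        [np.stack([c, s], -1), np.stack([-s, c], -1)], axis=-2
    )  # (N,2,2) R^T
    dRT = np.stack(
        [np.stack([-s, c], -1), np.stack([-c, -s], -1)], axis=-2
    )  # d(R^T)/dtheta
    r = np.einsum("nij,nj->ni", RT, d) - z
    E = np.zeros((len(sel), 2, 3))
    E[:, :, :2] = -RT
    E[:, :, 2] = np.einsum("nij,nj->ni", dRT, d)
    F = RT
    return r, E, F, Q, pidx, lidx


def _gps_terms_norot(poses: np.ndarray, gps: Sequence[GpsObservation], weights):
    idx = np.array([o.pose_index for o in gps])
    coords = np.stack([o.coord for o in gps])
    Q = np.stack([o.info for o in gps])
    if weights is not None:
        Q = Q * np.asarray(weights, dtype=float)[:, None, None]
    r = poses[idx, :2] - coords
    return r, Q, idx


def assemble_refinement_system(
    aug: AugmentedState,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    obs: Sequence[StemObservation],
    assignment: ClusterAssignment,
    gps_weights: np.ndarray | None = None,
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sparse normal equations over (poses, stem centers).

    The layout is pose blocks first (3 per pose), then 2 per stem center.
    The global-orientation row/column is absent: the GPS translation block is
    the 2x2 identity.  Outlier observations (label 0) contribute nothing.
    """
    n = len(aug.poses)
    L = len(aug.centers)
    dim = 3 * n + 2 * L
    rows, cols, vals = [], [], []
    b = np.zeros(dim)

    if len(edges) > 0:
        r, A, B, Q = _odometry_terms(aug.poses, edges)
        m = len(edges)
        Je = np.concatenate([A, B], axis=2)
        Hblk = np.einsum("mji,mjl,mlk->mik", Je, Q, Je)
        bblk = np.einsum("mji,mjk,mk->mi", Je, Q, r)
        block_cols = 3 * np.arange(m)[:, None] + np.arange(6)[None, :]
        rows.append(np.repeat(block_cols, 6, axis=1).ravel())
        cols.append(np.tile(block_cols, (1, 6)).ravel())
        vals.append(Hblk.ravel())
        np.add.at(b, block_cols.ravel(), bblk.ravel())

    if len(gps) > 0:
        r, Q, idx = _gps_terms_norot(aug.poses, gps, gps_weights)
        # Jacobian is (I2, 0) on the pose translation: H and b reduce to Q
        Hblk = Q
        bblk = np.einsum("gij,gj->gi", Q, r)
        block_cols = 3 * idx[:, None] + np.arange(2)[None, :]
        rows.append(np.repeat(block_cols, 2, axis=1).ravel())
        cols.append(np.tile(block_cols, (1, 2)).ravel())
        vals.append(Hblk.ravel())
        np.add.at(b, block_cols.ravel(), bblk.ravel())

    if len(obs) > 0 and assignment.n_clusters > 0:
        r, E, F, Q, pidx, lidx = _stem_terms(aug, obs, assignment)
        N = len(r)
        Jo = np.zeros((N, 2, 5))
        Jo[:, :, :3] = E
        Jo[:, :, 3:] = F
        Hblk = np.einsum("nji,njl,nlk->nik", Jo, Q, Jo)
        bblk = np.einsum("nji,njk,nk->ni", Jo, Q, r)
        block_cols = np.concatenate(
            [
                3 * pidx[:, None] + np.arange(3)[None, :],
                3 * n + 2 * lidx[:, None] + np.arange(2)[None, :],
            ],
            axis=1,
        )
        rows.append(np.repeat(block_cols, 5, axis=1).ravel())
        cols.append(np.tile(block_cols, (1, 5)).ravel())
        vals.append(Hblk.ravel())
        np.add.at(b, block_cols.ravel(), bblk.ravel())

    if not vals:
        return sp.csc_matrix((dim, dim)), b
    H = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    ).tocsc()
    return H, b


def _refinement_objective(
    aug: AugmentedState,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    obs: Sequence[StemObservation],
    assignment: ClusterAssignment,
    gps_weights,
) -> float:
    total = 0.0
    if len(edges) > 0:
        r, _, _, Q = _odometry_terms(aug.poses, edges)
        total += float(np.einsum("mi,mij,mj->", r, Q, r))
    if len(gps) > 0:
        r, Q, _ = _gps_terms_norot(aug.poses, gps, gps_weights)
        total += float(np.einsum("gi,gij,gj->", r, Q, r))
    if len(obs) > 0 and assignment.n_clusters > 0:
        r, _, _, Q, _, _ = _stem_terms(aug, obs, assignment)
        total += float(np.einsum("ni,nij,nj->", r, Q, r))
    return total


@dataclass
class RefinementResult:
    poses: np.ndarray
    stem_map: StemMap
    pre_map: StemMap
    assignment: ClusterAssignment
    history: dict


def refine_map(
    aligned: np.ndarray,
    edges: Sequence[OdometryEdge],
    gps: Sequence[GpsObservation],
    obs: Sequence[StemObservation],
    radius: float = 1.0,
    min_pts: int = 10,
    cfg: LMConfig | None = None,
) -> RefinementResult:
    """Associate detections into landmarks and jointly refine poses and stems.

    ``aligned`` are globally aligned poses; ``gps`` coordinates must be in
    the same frame as the poses.  Pipeline: transform observations to world
    coordinates, cluster, initialize centers at cluster means, then optimize
    the joint objective with the LM schedule.  Returns refined poses and the
    stem map with post-refinement empirical cluster covariances (the pre-
    refinement map is kept for comparison).
    """
    cfg = cfg or LMConfig()
    aligned = np.asarray(aligned, dtype=float)
    n = len(aligned)

    # work in a local frame near the origin to keep coordinates small
    origin = aligned[0, :2].copy()
    poses0 = aligned.copy()
    poses0[:, :2] -= origin
    gps_local = [
        GpsObservation(g.coord - origin, g.info, g.pose_index, g.pdop) for g in gps
    ]

    world = observations_to_world(obs, poses0)
    assignment = dbscan_cluster(world, radius, min_pts)
    pre_map_local = cluster_centers(world, assignment)
    aug0 = AugmentedState(poses=poses0, centers=pre_map_local.centers.copy())

    def build(x: np.ndarray):
        aug = AugmentedState.from_vector(x, n)
        weights = None
        if cfg.robust_gps and len(gps_local) > 0:
            r, _, _ = _gps_terms_norot(aug.poses, gps_local, None)
            norms = np.linalg.norm(r, axis=1)
            scale = cfg.mad_k * np.median(norms)
            if scale > 0:
                u = norms / scale
                weights = np.where(
                    u <= cfg.tukey_c, (1 - (u / cfg.tukey_c) ** 2) ** 2, 0.0
                )
        H, b = assemble_refinement_system(
            aug, edges, gps_local, obs, assignment, weights
        )
        obj = _refinement_objective(
            aug, edges, gps_local, obs, assignment, weights
        )

        def eval_obj(x_new):
            return _refinement_objective(
                AugmentedState.from_vector(x_new, n),
                edges,
                gps_local,
                obs,
                assignment,
                weights,
            )

        return H, b, obj, eval_obj

    x_opt, history = lm_minimize(aug0.as_vector(), build, cfg)
    aug_opt = AugmentedState.from_vector(x_opt, n)

    refined_poses = aug_opt.poses.copy()
    refined_poses[:, :2] += origin

    world_post = observations_to_world(obs, aug_opt.poses)
    post_covs = np.empty_like(pre_map_local.covariances)
    for k, lab in enumerate(assignment.label_set):
        member = world_post[assignment.labels == lab]
        post_covs[k] = np.cov(member, rowvar=False, ddof=1)

    pre_map = StemMap(
        centers=pre_map_local.centers + origin,
        counts=pre_map_local.counts,
        covariances=pre_map_local.covariances,
    )
    stem_map = StemMap(
        centers=aug_opt.centers + origin,
        counts=pre_map_local.counts.copy(),
        covariances=post_covs,
    )
    return RefinementResult(
        poses=refined_poses,
        stem_map=stem_map,
        pre_map=pre_map,
        assignment=assignment,
        history=history,
    )
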