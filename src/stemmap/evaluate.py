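"""Trajectory and stem-map evaluation utilities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "trajectory_rmse",
    "rigid_align_2d",
    "StemMapEvaluation",
    "evaluate_stem_map",
    "gps_interpolation_baseline",
]


def trajectory_rmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """RMSE over per-pose Euclidean position errors (headings excluded)."""
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if len(est) != len(tru):
        raise ValueError(f"length mismatch: {len(est)} vs {len(tru)}")
    d = est[:, :2] - tru[:, :2]
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def rigid_align_2d(points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Best-fit rigid transform (rotation + translation, no scale) of
    ``points`` onto ``ref``; returns the transformed points.

    Used to give dead-reckoning baselines their most favorable placement
    before computing an error against ground truth.
    """
    P = np.asarray(points, dtype=float)[:, :2]
    Q = np.asarray(ref, dtype=float)[:, :2]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    S = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return Pc @ R.T + Q.mean(axis=0)


@dataclass
class StemMapEvaluation:
    rmse: float
    n_matched: int
    duplicates: int
    false_positives: int
    matches: list[tuple[int, int]]  # (prediction index, truth index)


def evaluate_stem_map(
    predicted: np.ndarray, truth: np.ndarray, max_dist: float = 5.0
) -> StemMapEvaluation:
    """Associate predicted stems with ground truth and score the map.

    Mutual-nearest-neighbor pairs within ``max_dist`` are matches (RMSE over
    those); extra predictions whose nearest truth stem is already matched
    count as duplicates; predictions with no truth stem within range are
    false positives.
    """
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    tru = np.atleast_2d(np.asarray(truth, dtype=float))
    if len(pred) == 0 or len(tru) == 0:
        raise ValueError("predicted and truth maps must be non-empty")
    tree_t = cKDTree(tru)
    tree_p = cKDTree(pred)
    d_pt, nearest_t = tree_t.query(pred)
    _, nearest_p = tree_p.query(tru)

    matches = []
    duplicates = 0
    false_positives = 0
    for p in range(len(pred)):
        t = nearest_t[p]
        if d_pt[p] > max_dist:
            false_positives += 1
        elif nearest_p[t] == p:
            matches.append((p, int(t)))
        else:
            duplicates += 1
    if matches:
        err = np.array([pred[p] - tru[t] for p, t in matches])
        rmse = float(np.sqrt(np.mean(np.sum(err**2, axis=1))))
    else:
        rmse = float("nan")
    return StemMapEvaluation(
        rmse=rmse,
        n_matched=len(matches),
        duplicates=duplicates,
        false_positives=false_positives,
        matches=matches,
    )


def gps_interpolation_baseline(
    truth: np.ndarray,
    gps_coords: np.ndarray,
    pose_indices: np.ndarray,
) -> float:
    """RMSE of a piecewise-linear interpolation of the GPS fixes.

    Positions between corresponded poses are linearly interpolated in pose
    index; poses outside the first/last fix are clamped to the end fixes.
    """
    truth = np.asarray(truth, dtype=float)
    coords = np.asarray(gps_coords, dtype=float)
    idx = np.asarray(pose_indices, dtype=float)
    n = len(truth)
    interp = np.stack(
        [
            np.interp(np.arange(n), idx, coords[:, 0]),
            np.interp(np.arange(n), idx, coords[:, 1]),
        ],
        axis=-1,
    )
    return trajectory_rmse(np.column_stack([interp, np.zeros(n)]), truth)
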