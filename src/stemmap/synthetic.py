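"""Seeded generators for every input the pipeline consumes.

The generators emulate a hand-held stereo survey of a forest stand: a smooth
constant-speed walking path of roughly a kilometer sampled at video rate,
tree stems scattered through a corridor around the path, per-frame stem
detections with range-dependent noise, GPS fixes with Gaussian noise,
optional uniform outliers and intermittent sampling, and rendered
image pairs with exact depth for testing the visual odometry front end.

All generators are pure functions of their spec and seed: repeated calls are
bit-identical.  Sub-streams are split from the spec seed so each scenario
ingredient (path shape, stems, GPS noise, detection noise) is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CameraIntrinsics, Twist6, pose2_relative, se3_exp, wrap_angle
from .global_alignment import (
    GpsObservation,
    OdometryEdge,
    default_gps_info,
    default_odometry_info,
)
from .stem_refinement import StemObservation, observation_sigma

__all__ = [
    "WorldSpec",
    "GpsNoiseSpec",
    "SyntheticWorld",
    "simulate_world",
    "exact_odometry_edges",
    "add_odometry_noise",
    "simulate_gps_track",
    "simulate_stem_observations",
    "StereoScene",
    "render_stereo_pair",
    "default_intrinsics",
]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class WorldSpec:
    """Scale and sampling of the synthetic stand survey.

    Defaults mirror the emulated field campaign: a ~1115 m walking path
    recorded at 10 frames per second, ~140 stems in the surveyed corridor.
    """

    seed: int = 0
    path_length_m: float = 1115.0
    frame_rate: float = 10.0
    speed_mps: float = 1.2
    curvature_max: float = 0.03  # rad/m; minimum turning radius ~33 m
    curvature_components: int = 4
    stem_count: int = 140
    stand_corridor_m: float = 15.0
    stem_min_spacing_m: float = 2.5
    camera_fov_rad: float = 1.57
    max_detection_range_m: float = 12.0
    min_detection_range_m: float = 0.5
    origin: tuple[float, float] = (2000.0, 1000.0)
    initial_heading: float | None = None  # None: random in (-pi, pi]

    def __post_init__(self) -> None:
        if min(self.path_length_m, self.frame_rate, self.speed_mps) <= 0:
            raise ValueError("lengths and rates must be positive")


@dataclass(frozen=True)
class GpsNoiseSpec:
    """GPS degradation scenario: noise scale, outliers, sampling pattern."""

    sigma_m: float = 5.0
    outlier_fraction: float = 0.0
    outlier_range_m: tuple[float, float] = (0.0, 200.0)
    mode: str = "dense"  # "dense" or "intermittent"
    interval_m: float = 100.0
    seed: int = 0
    info_sigma_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.mode not in ("dense", "intermittent"):
            raise ValueError("mode must be 'dense' or 'intermittent'")


@dataclass
class SyntheticWorld:
    trajectory: np.ndarray  # (n, 3) true poses
    stems: np.ndarray  # (S, 2) true stem positions
    edges: list[OdometryEdge]  # exact relative motions
    spec: WorldSpec = field(repr=False, default=None)


def simulate_world(
    spec: WorldSpec, odometry_info: np.ndarray | None = None
) -> SyntheticWorld:
    """Smooth bounded-curvature trajectory, stems, and exact odometry edges.

    The heading rate along the path is a random low-frequency sinusoid
    mixture scaled to the curvature bound; stems are placed uniformly within
    the corridor around the path with a minimum spacing larger than twice
    the clustering radius.  Edges carry the exact relative motions (noise is
    added separately) and the supplied information matrix.
    """
    rng_path, rng_stems = _streams(spec.seed, 2)
    step = spec.speed_mps / spec.frame_rate
    n_steps = int(round(spec.path_length_m / step))
    s = np.arange(n_steps) * step

    L = spec.path_length_m
    kappa = np.zeros(n_steps)
    for j in range(1, spec.curvature_components + 1):
        amp = rng_path.normal()
        phase = rng_path.uniform(0, 2 * np.pi)
        kappa += amp * np.sin(2 * np.pi * j * s / L + phase)
    peak = np.max(np.abs(kappa))
    if peak > 0:
        kappa *= spec.curvature_max / peak

    theta0 = (
        rng_path.uniform(-np.pi, np.pi)
        if spec.initial_heading is None
        else spec.initial_heading
    )
    headings = wrap_angle(theta0 + np.concatenate([[0.0], np.cumsum(kappa[:-1] * step)]))
    dxy = step * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    xy = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(dxy, axis=0)], axis=0
    ) + np.asarray(spec.origin)
    trajectory = np.column_stack(
        [xy, np.concatenate([headings, headings[-1:]])]
    )

    stems = _place_stems(trajectory, spec, rng_stems)
    info = (
        odometry_info if odometry_info is not None else default_odometry_info()
    )
    edges = exact_odometry_edges(trajectory, info)
    return SyntheticWorld(trajectory=trajectory, stems=stems, edges=edges, spec=spec)


def _place_stems(
    trajectory: np.ndarray, spec: WorldSpec, rng: np.random.Generator
) -> np.ndarray:
    from scipy.spatial import cKDTree

    path = trajectory[:, :2]
    tree = cKDTree(path[:: max(1, len(path) // 2000)])
    lo = path.min(axis=0) - spec.stand_corridor_m
    hi = path.max(axis=0) + spec.stand_corridor_m
    stems: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * spec.stem_count
    while len(stems) < spec.stem_count and attempts < max_attempts:
        attempts += 1
        cand = rng.uniform(lo, hi)
        d_path, _ = tree.query(cand)
        if d_path > spec.stand_corridor_m or d_path < 0.8:
            continue  # outside the surveyed corridor, or on the path itself
        if stems and np.min(np.linalg.norm(np.array(stems) - cand, axis=1)) < (
            spec.stem_min_spacing_m
        ):
            continue
        stems.append(cand)
    return np.array(stems) if stems else np.zeros((0, 2))


def exact_odometry_edges(
    trajectory: np.ndarray, info: np.ndarray
) -> list[OdometryEdge]:
    """Relative body-frame motions between consecutive poses of a trajectory."""
    trajectory = np.asarray(trajectory, dtype=float)
    return [
        OdometryEdge(i, pose2_relative(trajectory[i], trajectory[i + 1]), info)
        for i in range(len(trajectory) - 1)
    ]


def add_odometry_noise(
    edges: Sequence[OdometryEdge],
    sigma_t: float,
    sigma_theta: float,
    seed: int,
    bias_sigma_theta: float = 0.0,
    info: np.ndarray | None = None,
) -> list[OdometryEdge]:
    """Perturb edge motions with odometry drift noise.

    The drift model is i.i.d. Gaussian noise per edge plus, optionally, a
    constant per-run heading-rate bias of magnitude ``bias_sigma_theta``
    with random sign — the systematic component (calibration error,
    anisotropic texture) that makes real visual odometry curve away
    coherently rather than wander.  The returned edges carry information
    consistent with the i.i.d. part unless an explicit matrix is supplied.
    """
    rng = np.random.default_rng(seed)
    bias = bias_sigma_theta * rng.choice([-1.0, 1.0]) if bias_sigma_theta > 0 else 0.0
    info = info if info is not None else default_odometry_info(sigma_t, sigma_theta)
    out = []
    for e in edges:
        noise = np.array(
            [
                rng.normal(0, sigma_t),
                rng.normal(0, sigma_t),
                rng.normal(0, sigma_theta) + bias,
            ]
        )
        out.append(OdometryEdge(e.i, e.motion + noise, info))
    return out


def simulate_gps_track(
    trajectory: np.ndarray, spec: GpsNoiseSpec
) -> tuple[list[GpsObservation], list[tuple[int, int]]]:
    """GPS fixes along the trajectory with the scenario's degradations.

    Dense mode emits one fix per pose.  Intermittent mode keeps the first
    pose, the last pose, and one uniformly drawn pose per full interval of
    ``interval_m`` of interior path (12 fixes on a ~1115 m path at 100 m
    intervals).  Fixes get i.i.d. per-axis Gaussian noise; a random fraction
    is additionally displaced by a uniform radial outlier.
    """
    rng_noise, rng_pick, rng_out = _streams(spec.seed, 3)
    trajectory = np.asarray(trajectory, dtype=float)
    n = len(trajectory)
    seg = np.linalg.norm(np.diff(trajectory[:, :2], axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]

    if spec.mode == "dense":
        pose_idx = np.arange(n)
    else:
        picks = [0]
        k = 1
        while (k + 1) * spec.interval_m < total:
            lo = np.searchsorted(arclen, k * spec.interval_m)
            hi = np.searchsorted(arclen, (k + 1) * spec.interval_m)
            if hi > lo:
                picks.append(int(rng_pick.integers(lo, hi)))
            k += 1
        picks.append(n - 1)
        pose_idx = np.unique(picks)

    coords = trajectory[pose_idx, :2] + rng_noise.normal(
        0, spec.sigma_m, size=(len(pose_idx), 2)
    )
    n_out = int(round(spec.outlier_fraction * len(pose_idx)))
    if n_out > 0:
        which = rng_out.choice(len(pose_idx), size=n_out, replace=False)
        mag = rng_out.uniform(*spec.outlier_range_m, size=n_out)
        ang = rng_out.uniform(0, 2 * np.pi, size=n_out)
        coords[which] += mag[:, None] * np.stack(
            [np.cos(ang), np.sin(ang)], axis=-1
        )

    info = default_gps_info(max(spec.sigma_m, spec.info_sigma_floor))
    gps = [
        GpsObservation(coord=c, info=info, pose_index=int(i))
        for c, i in zip(coords, pose_idx)
    ]
    corr = [(int(i), k) for k, i in enumerate(pose_idx)]
    return gps, corr


def simulate_stem_observations(
    trajectory: np.ndarray,
    stems: np.ndarray,
    spec: WorldSpec,
    noise_scale: float = 1.0,
) -> list[StemObservation]:
    """Per-frame camera-frame stem detections within the sensing frustum.

    A stem is observed from a pose when it lies in front of the camera,
    within the detection range, and within the horizontal field of view.
    Observations get zero-mean Gaussian noise with the range-dependent
    standard deviation ``0.1 + 0.05 d`` (scaled by ``noise_scale``), and an
    information matrix consistent with the generating sigma.
    """
    (rng,) = _streams(spec.seed + 1_000_003, 1)
    trajectory = np.asarray(trajectory, dtype=float)
    stems = np.asarray(stems, dtype=float)
    if len(stems) == 0:
        return []
    th = trajectory[:, 2]
    c, s = np.cos(th), np.sin(th)
    diff = stems[None, :, :] - trajectory[:, None, :2]  # (n, S, 2)
    fwd = c[:, None] * diff[:, :, 0] + s[:, None] * diff[:, :, 1]
    lat = -s[:, None] * diff[:, :, 0] + c[:, None] * diff[:, :, 1]
    rng_d = np.hypot(fwd, lat)
    visible = (
        (fwd > spec.min_detection_range_m)
        & (rng_d <= spec.max_detection_range_m)
        & (np.abs(np.arctan2(lat, fwd)) <= spec.camera_fov_rad / 2)
    )
    pose_ids, stem_ids = np.nonzero(visible)
    d = rng_d[pose_ids, stem_ids]
    sigma = observation_sigma(d)
    noise = rng.normal(size=(len(d), 2)) * (noise_scale * sigma)[:, None]
    fwd_obs = np.maximum(fwd[pose_ids, stem_ids] + noise[:, 0], 0.01)
    lat_obs = lat[pose_ids, stem_ids] + noise[:, 1]

    obs: list[StemObservation] = []
    counter: dict[int, int] = {}
    for p, fo, lo_, sg in zip(pose_ids, fwd_obs, lat_obs, sigma):
        q = counter.get(p, 0)
        counter[p] = q + 1
        obs.append(
            StemObservation(
                pose_index=int(p),
                obs_index=q,
                offset=np.array([fo, lo_]),
                info=np.eye(2) / sg**2,
            )
        )
    return obs


def default_intrinsics() -> CameraIntrinsics:
    """Calibration of the emulated stereo rig at VO resolution (240x320)."""
    return CameraIntrinsics(f=350.0, cu=160.0, cv=120.0, baseline=0.12,
                            width=320, height=240)


@dataclass(frozen=True)
class StereoScene:
    """Piecewise fronto-parallel textured scene for rendering image pairs.

    The image is split into vertical stripes, each a fronto-parallel plane
    at the depth implied by an integer disparity, so the ground-truth
    disparity map is exact.  The texture is a smooth sinusoid mixture over
    the plane coordinates, band-limited but gradient-rich at pixel scale.
    """

    width: int = 320
    height: int = 240
    disparities: tuple[int, ...] = (42, 14, 28, 6, 21, 10, 5, 8)
    seed: int = 7

    def stripe_bounds(self) -> np.ndarray:
        edges = np.linspace(0, self.width, len(self.disparities) + 1)
        return np.round(edges).astype(int)


def _texture(scene: StereoScene):
    """Band-limited sinusoid mixture over plane coordinates.

    Frequencies are scaled by 1/z so the pixel-scale wavelength (roughly
    40-400 px) is depth-independent: coarse enough to give single-scale
    photometric alignment a wide convergence basin (there is no image
    pyramid), fine enough to constrain all six motion parameters.
    """
    rng = np.random.default_rng(scene.seed)
    n_waves = 6
    freqs = rng.uniform(5, 30, size=(n_waves, 2)) * rng.choice(
        [-1, 1], size=(n_waves, 2)
    )
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = np.array([40.0, 32.0, 26.0, 20.0, 16.0, 12.0])

    def tex(X, Y, z):
        X = np.asarray(X, float)
        val = np.full_like(X, 128.0)
        scale = 2.0 / np.asarray(z, float)
        for (fx, fy), ph, a in zip(freqs, phases, amps):
            val = val + a * np.sin((fx * X + fy * Y) * scale + ph + 2.0 * z)
        return val

    return tex


def render_stereo_pair(
    scene: StereoScene, motion: Twist6, K: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (reference image, moved-camera image, true disparity map).

    ``motion`` uses the warp convention: ``se3_exp(motion)`` maps
    reference-camera coordinates into the coordinates of the second camera,
    matching the twist that :func:`stemmap.direct_vo.estimate_egomotion`
    recovers.  The second image is evaluated analytically by intersecting
    each pixel ray with the stripe planes (nearest hit wins), which is the
    exact limit of warping the first image with perfect resampling.
    Disocclusions are filled with a flat background value.
    """
    tex = _texture(scene)
    bounds = scene.stripe_bounds()
    h, w = scene.height, scene.width
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))

    depths = np.array([K.f * K.baseline / d for d in scene.disparities])
    stripe_of_u = np.searchsorted(bounds, np.arange(w), side="right") - 1
    stripe_of_u = np.clip(stripe_of_u, 0, len(scene.disparities) - 1)

    z_ref = depths[stripe_of_u][None, :] * np.ones((h, 1))
    X = (u - K.cu) * z_ref / K.f
    Y = (v - K.cv) * z_ref / K.f
    ref = tex(X, Y, z_ref)
    disparity = np.broadcast_to(
        np.asarray(scene.disparities, dtype=np.int32)[stripe_of_u][None, :], (h, w)
    ).copy()

    T = se3_exp(motion)
    Rt = T.rot.T
    t = T.trans
    # ray direction per second-camera pixel, expressed in the reference frame
    d_cam = np.stack([(u - K.cu) / K.f, (v - K.cv) / K.f, np.ones_like(u)], -1)
    d_ref = d_cam @ Rt.T  # == (R^T d) per pixel
    o_ref = -Rt @ t  # second-camera center in reference coordinates

    moved = np.full((h, w), 64.0)
    moved_disp = np.zeros((h, w), dtype=np.int32)
    best_lambda = np.full((h, w), np.inf)
    for k, disp in enumerate(scene.disparities):
        z_s = depths[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = (z_s - o_ref[2]) / d_ref[:, :, 2]
        hit_x = o_ref[0] + lam * d_ref[:, :, 0]
        hit_y = o_ref[1] + lam * d_ref[:, :, 1]
        u_ref = K.f * hit_x / z_s + K.cu
        ok = (
            (lam > 0)
            & np.isfinite(lam)
            & (u_ref >= bounds[k])
            & (u_ref < bounds[k + 1])
            & (lam < best_lambda)
        )
        vals = tex(hit_x, hit_y, z_s)
        moved = np.where(ok, vals, moved)
        z_in_second = lam * d_cam[:, :, 2]  # depth along the second optical axis
        moved_disp = np.where(
            ok, np.rint(K.f * K.baseline / np.maximum(z_in_second, 1e-9)), moved_disp
        ).astype(np.int32)
        best_lambda = np.where(ok, lam, best_lambda)
    return ref, moved, disparity
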