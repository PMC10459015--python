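"""End-to-end pipeline: VO (optional) -> global alignment -> refinement."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as smio
from .direct_vo import RobustConfig, estimate_egomotion, make_frame
from .geometry import se3_exp, se3_log, se3_to_se2_motion
from .global_alignment import (
    GlobalState,
    LMConfig,
    OdometryEdge,
    anchor_gps,
    build_graph,
    correspond_by_timestamp,
    default_gps_info,
    default_odometry_info,
    GpsObservation,
    lm_optimize,
    recover_global,
)
from .stem_refinement import refine_map

__all__ = ["RunConfig", "PipelineError", "PipelineReport", "run_pipeline", "run_vo_sequence"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys in config files are rejected."""

    gps: str | None = None
    detections: str | None = None
    odometry: str | None = None
    frames_dir: str | None = None
    calibration: str | None = None
    output_dir: str = "stemmap_out"
    frame_rate: float = 10.0
    vo_percent: float = 25.0
    vo_robust: bool = True
    odom_sigma_t: float = 0.1
    odom_sigma_theta: float = 0.005
    gps_sigma: float = 5.0
    use_pdop: bool = False
    robust_gps: bool = True
    lm_step_tol: float = 1e-3
    lm_max_iters: int = 100
    cluster_radius: float = 1.0
    cluster_min_pts: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineReport:
    trajectory: np.ndarray
    stem_map: object | None
    summary: dict = field(default_factory=dict)


def run_vo_sequence(frames_dir, K, percent=25.0, robust=True):
    """Run direct VO over a directory of image/disparity pairs.

    Expects sorted pairs ``frame_*.png`` / ``disp_*.png``.  Returns per-pair
    planar motions (camera pose increments) and the raw warp twists.
    """
    frames_dir = Path(frames_dir)
    imgs = sorted(frames_dir.glob("frame_*.png"))
    disps = sorted(frames_dir.glob("disp_*.png"))
    if len(imgs) < 2 or len(imgs) != len(disps):
        raise PipelineError("vo", "need matching frame_*/disp_* sequences")
    cfg = RobustConfig(robust=robust)
    motions, twists = [], []
    prev = make_frame(smio.read_image(imgs[0]), smio.read_disparity(disps[0]), K)
    for img_path, disp_path in zip(imgs[1:], disps[1:]):
        cur = make_frame(smio.read_image(img_path), smio.read_disparity(disp_path), K)
        res = estimate_egomotion(prev, cur, K, cfg, percent=percent)
        # VO solves for the warp (ref -> input coordinates); the camera pose
        # increment is its inverse
        pose_twist = se3_log(se3_exp(res.xi).inverse())
        motions.append(np.asarray(se3_to_se2_motion(pose_twist)))
        twists.append(res.xi.as_array())
        prev = cur
    return np.array(motions), np.array(twists)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute odometry ingestion, global alignment, and local refinement."""
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    # --- odometry ---
    if config.frames_dir is not None:
        if config.calibration is None:
            raise PipelineError("config", "frames supplied without calibration")
        K = smio.read_calibration(config.calibration)
        motions, twists = run_vo_sequence(
            config.frames_dir, K, config.vo_percent, config.vo_robust
        )
        smio.write_odometry(out_dir / "odometry.csv", motions, twists)
    elif config.odometry is not None:
        motions = smio.read_odometry(config.odometry)
    else:
        raise PipelineError("config", "need either frames_dir or odometry")
    info = default_odometry_info(config.odom_sigma_t, config.odom_sigma_theta)
    edges = [OdometryEdge(i, m, info) for i, m in enumerate(motions)]
    poses0 = build_graph(edges)
    summary["stages"]["odometry"] = {"n_poses": len(poses0)}

    # --- GPS ---
    if config.gps is None:
        raise PipelineError("config", "a GPS track is required for alignment")
    gps_df = smio.read_gps_track(config.gps)
    frame_times = np.arange(len(poses0)) / config.frame_rate
    corr = correspond_by_timestamp(
        frame_times, gps_df["timestamp"].to_numpy(dtype=float)
    )
    if len(corr) < 2:
        raise PipelineError("align", "fewer than two matched GPS fixes")
    gps = []
    for i, k in corr:
        pdop = float(gps_df["pdop"].iloc[k]) if "pdop" in gps_df.columns else None
        gps.append(
            GpsObservation(
                coord=gps_df[["easting_m", "northing_m"]].iloc[k].to_numpy(float),
                info=default_gps_info(config.gps_sigma, pdop, config.use_pdop),
                pose_index=i,
                pdop=pdop,
            )
        )

    # --- global alignment ---
    anchored, g0 = anchor_gps(gps)
    lm_cfg = LMConfig(
        step_tol=config.lm_step_tol,
        max_iters=config.lm_max_iters,
        robust_gps=config.robust_gps,
    )
    state, hist = lm_optimize(
        GlobalState(phi=0.0, poses=poses0, anchor=g0), edges, anchored, lm_cfg
    )
    aligned = recover_global(state)
    smio.write_trajectory(out_dir / "trajectory_aligned.csv", aligned)
    summary["stages"]["align"] = {
        "iterations": len(hist["objective"]),
        "phi": state.phi,
        "final_objective": hist["objective"][-1] if hist["objective"] else None,
    }

    # --- local refinement ---
    stem_map = None
    trajectory = aligned
    if config.detections is not None:
        obs = smio.read_detections(config.detections)
        result = refine_map(
            aligned,
            edges,
            gps,
            obs,
            radius=config.cluster_radius,
            min_pts=config.cluster_min_pts,
            cfg=lm_cfg,
        )
        trajectory = result.poses
        stem_map = result.stem_map
        smio.write_trajectory(out_dir / "trajectory_refined.csv", trajectory)
        smio.write_stem_map(out_dir / "stem_map.csv", stem_map)
        smio.write_stem_map_geojson(out_dir / "stem_map.geojson", stem_map)
        summary["stages"]["refine"] = {
            "iterations": len(result.history["objective"]),
            "n_stems": len(stem_map.centers),
            "n_observations": len(obs),
            "n_outlier_observations": int(np.sum(result.assignment.labels == 0)),
        }

    summary["elapsed_s"] = time.time() - t_start
    with open(out_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return PipelineReport(trajectory=trajectory, stem_map=stem_map, summary=summary)
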