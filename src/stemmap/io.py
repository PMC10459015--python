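"""File formats: calibration, GPS tracks, detections, trajectories, maps.

All tabular formats are header-carrying delimited text (CSV); images and
disparity maps are PNG/PGM (disparity as 16-bit single-channel, 0 = invalid).
Coordinates are planar UTM meters in a single, caller-declared zone.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import CameraIntrinsics
from .stem_refinement import StemMap, StemObservation, default_stem_info

__all__ = [
    "read_calibration",
    "write_calibration",
    "read_gps_track",
    "write_gps_track",
    "read_detections",
    "write_detections",
    "read_trajectory",
    "write_trajectory",
    "read_odometry",
    "write_odometry",
    "write_stem_map",
    "read_stem_map",
    "write_stem_map_geojson",
    "read_image",
    "write_image",
    "read_disparity",
    "write_disparity",
]


def read_calibration(path) -> CameraIntrinsics:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {"f", "cu", "cv", "baseline_m", "width", "height"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
    return CameraIntrinsics(
        f=float(data["f"]),
        cu=float(data["cu"]),
        cv=float(data["cv"]),
        baseline=float(data["baseline_m"]),
        width=data.get("width"),
        height=data.get("height"),
    )


def write_calibration(path, K: CameraIntrinsics) -> None:
    data = {"f": K.f, "cu": K.cu, "cv": K.cv, "baseline_m": K.baseline}
    if K.width is not None:
        data["width"] = int(K.width)
    if K.height is not None:
        data["height"] = int(K.height)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_gps_track(path) -> pd.DataFrame:
    """Columns: timestamp, easting_m, northing_m, optional pdop."""
    df = pd.read_csv(path)
    required = {"timestamp", "easting_m", "northing_m"}
    if not required <= set(df.columns):
        raise ValueError(f"GPS track needs columns {sorted(required)}")
    return df


def write_gps_track(path, timestamps, coords, pdop=None) -> None:
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(
        {
            "timestamp": np.asarray(timestamps, dtype=float),
            "easting_m": coords[:, 0],
            "northing_m": coords[:, 1],
        }
    )
    if pdop is not None:
        df["pdop"] = np.asarray(pdop, dtype=float)
    df.to_csv(path, index=False)


def read_detections(path) -> list[StemObservation]:
    """Columns: frame_index, forward_m, lateral_m, optional range_m."""
    df = pd.read_csv(path)
    required = {"frame_index", "forward_m", "lateral_m"}
    if not required <= set(df.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    obs = []
    counters: dict[int, int] = {}
    for row in df.itertuples(index=False):
        frame = int(row.frame_index)
        q = counters.get(frame, 0)
        counters[frame] = q + 1
        rng = (
            float(row.range_m)
            if "range_m" in df.columns
            else float(np.hypot(row.forward_m, row.lateral_m))
        )
        obs.append(
            StemObservation(
                pose_index=frame,
                obs_index=q,
                offset=np.array([row.forward_m, row.lateral_m], dtype=float),
                info=default_stem_info(rng),
            )
        )
    return obs


def write_detections(path, obs: list[StemObservation]) -> None:
    df = pd.DataFrame(
        {
            "frame_index": [o.pose_index for o in obs],
            "forward_m": [o.offset[0] for o in obs],
            "lateral_m": [o.offset[1] for o in obs],
            "range_m": [float(np.linalg.norm(o.offset)) for o in obs],
        }
    )
    df.to_csv(path, index=False)


def read_trajectory(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x", "y", "theta"]].to_numpy(dtype=float)


def write_trajectory(path, poses: np.ndarray) -> None:
    poses = np.asarray(poses, dtype=float)
    pd.DataFrame(
        {
            "index": np.arange(len(poses)),
            "x": poses[:, 0],
            "y": poses[:, 1],
            "theta": poses[:, 2],
        }
    ).to_csv(path, index=False)


def read_odometry(path) -> np.ndarray:
    """Planar motion triples (dx, dy, dtheta) per consecutive frame pair."""
    df = pd.read_csv(path)
    return df[["dx", "dy", "dtheta"]].to_numpy(dtype=float)


def write_odometry(path, motions: np.ndarray, twists: np.ndarray | None = None):
    motions = np.asarray(motions, dtype=float)
    data = {
        "frame_index": np.arange(1, len(motions) + 1),
        "dx": motions[:, 0],
        "dy": motions[:, 1],
        "dtheta": motions[:, 2],
    }
    if twists is not None:
        twists = np.asarray(twists, dtype=float)
        for k, name in enumerate(["wx", "wy", "wz", "tx", "ty", "tz"]):
            data[name] = twists[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def write_stem_map(path, stem_map: StemMap) -> None:
    c = stem_map.covariances
    pd.DataFrame(
        {
            "stem_id": np.arange(1, len(stem_map.centers) + 1),
            "x": stem_map.centers[:, 0],
            "y": stem_map.centers[:, 1],
            "count": stem_map.counts,
            "cov_xx": c[:, 0, 0],
            "cov_xy": c[:, 0, 1],
            "cov_yy": c[:, 1, 1],
        }
    ).to_csv(path, index=False)


def read_stem_map(path) -> StemMap:
    df = pd.read_csv(path)
    covs = np.zeros((len(df), 2, 2))
    covs[:, 0, 0] = df["cov_xx"]
    covs[:, 0, 1] = covs[:, 1, 0] = df["cov_xy"]
    covs[:, 1, 1] = df["cov_yy"]
    return StemMap(
        centers=df[["x", "y"]].to_numpy(dtype=float),
        counts=df["count"].to_numpy(dtype=int),
        covariances=covs,
    )


def write_stem_map_geojson(path, stem_map: StemMap, crs: str = "UTM") -> None:
    features = []
    for k in range(len(stem_map.centers)):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [
                        float(stem_map.centers[k, 0]),
                        float(stem_map.centers[k, 1]),
                    ],
                },
                "properties": {
                    "stem_id": k + 1,
                    "observation_count": int(stem_map.counts[k]),
                    "covariance": [
                        [float(v) for v in row] for row in stem_map.covariances[k]
                    ],
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"crs_note": crs},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_image(path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=float)


def write_image(path, image: np.ndarray) -> None:
    img = np.clip(np.asarray(image, dtype=float), 0, 255)
    iio.imwrite(Path(path), img.astype(np.uint8))


def read_disparity(path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


def write_disparity(path, disparity: np.ndarray) -> None:
    d = np.asarray(disparity)
    if np.any(d < 0) or np.any(d > 65535):
        raise ValueError("disparity out of 16-bit range")
    iio.imwrite(Path(path), d.astype(np.uint16))
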