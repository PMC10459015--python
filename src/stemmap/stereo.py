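"""Disparity validation and depth recovery.

Disparity maps are integer-valued grids (disparity in pixels) where 0 marks
an invalid pixel.  Stereo matching itself is an external component: maps are
read from files or produced by a user-supplied matcher adapter.  Disparities
are kept as integers end-to-end (no sub-pixel refinement), so depth takes the
discrete values f*b/D.
"""

from __future__ import annotations

import numpy as np

from .geometry import CameraIntrinsics

__all__ = [
    "DisparityError",
    "as_disparity",
    "lr_consistency_filter",
    "depth_from_disparity",
    "disparity_from_matcher",
]


class DisparityError(ValueError):
    pass


def as_disparity(values: np.ndarray) -> np.ndarray:
    """Validate and coerce a grid into an integer disparity map (0 = invalid)."""
    d = np.asarray(values)
    if d.ndim != 2:
        raise DisparityError("disparity map must be 2-D")
    if not np.issubdtype(d.dtype, np.integer):
        di = np.rint(d).astype(np.int32)
        if not np.allclose(d, di):
            raise DisparityError("disparity map must be integer-valued")
        d = di
    if np.any(d < 0):
        raise DisparityError("disparity values must be non-negative")
    return d.astype(np.int32, copy=False)


def lr_consistency_filter(
    d_lr: np.ndarray, d_rl: np.ndarray, delta: int = 1
) -> np.ndarray:
    """Left/right consistency check.

    Keeps ``d_lr`` where ``|d_lr - d_rl| <= delta`` and zeroes (invalidates)
    the rest.  ``delta = 1`` is the operating default.
    """
    a = as_disparity(d_lr)
    b = as_disparity(d_rl)
    if a.shape != b.shape:
        raise DisparityError(
            f"disparity map shapes differ: {a.shape} vs {b.shape}"
        )
    if delta < 0:
        raise DisparityError("delta must be >= 0")
    keep = np.abs(a.astype(np.int64) - b.astype(np.int64)) <= delta
    return np.where(keep, a, 0).astype(np.int32)


def disparity_from_matcher(matcher, left: np.ndarray, right: np.ndarray,
                           delta: int = 1) -> np.ndarray:
    """Adapter for an external stereo matcher with occlusion handling.

    ``matcher(left, right)`` must return an integer left-to-right disparity
    map.  The right-to-left map is obtained by the reflection trick —
    mirroring both images along the column axis and swapping their roles —
    and the two are fused with the left/right consistency check, so occluded
    pixels (which smoothness-constrained matchers fill with arbitrary
    values) come out invalid.
    """
    d_lr = as_disparity(matcher(left, right))
    d_rl_flipped = as_disparity(matcher(right[:, ::-1], left[:, ::-1]))
    return lr_consistency_filter(d_lr, d_rl_flipped[:, ::-1], delta)


def depth_from_disparity(d: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Triangulated depth ``z = f*b/D`` in meters; NaN where D == 0.

    Depth is strictly positive exactly on the valid-disparity support; invalid
    pixels are carried as NaN so that any accidental use propagates loudly.
    """
    d = as_disparity(d)
    z = np.full(d.shape, np.nan, dtype=float)
    valid = d > 0
    z[valid] = K.f * K.baseline / d[valid]
    return z
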