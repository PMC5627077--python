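"""Finite-difference kinematics: velocity, speed and unit heading per fish.

Headings from near-zero velocities are dominated by tracking jitter and
would corrupt polarization and alignment statistics, so a heading is only
considered valid where the instantaneous speed reaches
``min_heading_speed`` (default 1 mm/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .io import TrajectorySet


@dataclass
class KinematicSeries:
    """Per-frame, per-individual kinematics in mm and seconds.

    ``valid_mask`` marks frames where a *heading* is usable (positions
    available and speed at or above the heading threshold);
    ``speed_valid`` marks frames where velocity/speed are defined at all.
    """

    velocity: np.ndarray  # (frames, individuals, 2) mm/s
    speed: np.ndarray  # (frames, individuals) mm/s
    heading: np.ndarray  # (frames, individuals, 2) unit vectors
    valid_mask: np.ndarray  # (frames, individuals) bool — heading usable
    speed_valid: np.ndarray  # (frames, individuals) bool — speed defined
    fps: float

    @property
    def heading_angle(self) -> np.ndarray:
        """Heading angles in radians (NaN where the heading is invalid)."""
        ang = np.arctan2(self.heading[..., 1], self.heading[..., 0])
        return np.where(self.valid_mask, ang, np.nan)


def compute_kinematics(
    t: TrajectorySet,
    method: str = "central",
    min_heading_speed: float = 1.0,
    smooth_window: int = 0,
) -> KinematicSeries:
    """Differentiate positions into velocities, speeds and unit headings.

    Parameters
    ----------
    method : {"central", "forward"}
        Central differences (default) estimate the velocity at frame k as
        ``(pos[k+1] - pos[k-1]) * fps / 2``; the first and last frames use
        one-sided differences.  "forward" uses ``pos[k+1] - pos[k]``
        everywhere (backward at the final frame).
    min_heading_speed : float
        Speed (mm/s) below which the heading is marked invalid.
    smooth_window : int
        Optional centred moving-average of the positions before
        differencing (0 = off, the default; no smoothing is assumed by the
        rest of the pipeline).  Only windows fully covered by measured
        fixes are smoothed.
    """
    if method not in ("central", "forward"):
        raise ConfigError(f"unknown differentiation method {method!r}")
    if t.n_frames < 3:
        raise DataError("need at least 3 frames to differentiate")
    pos = np.where(t.gap_mask[..., None], np.nan, t.positions)
    if smooth_window and smooth_window > 1:
        pos = _moving_average(pos, smooth_window)
    fps = t.fps
    vel = np.full_like(pos, np.nan)
    if method == "central":
        vel[1:-1] = (pos[2:] - pos[:-2]) * (fps / 2.0)
        vel[0] = (pos[1] - pos[0]) * fps
        vel[-1] = (pos[-1] - pos[-2]) * fps
    else:
        vel[:-1] = (pos[1:] - pos[:-1]) * fps
        vel[-1] = (pos[-1] - pos[-2]) * fps
    # a frame only carries kinematics if the fish was itself observed there
    # (pairing a heading with an unmeasured position would be meaningless)
    speed_valid = np.isfinite(vel).all(axis=2) & ~t.gap_mask
    speed = np.linalg.norm(np.nan_to_num(vel), axis=2)
    speed[~speed_valid] = np.nan
    valid = speed_valid & (speed >= min_heading_speed)
    heading = np.full_like(vel, np.nan)
    np.divide(vel, speed[..., None], out=heading, where=valid[..., None])
    for i in range(t.n_individuals):
        if not speed_valid[:, i].any():
            warnings.warn(
                f"individual {i} has no valid kinematics (fully masked)",
                stacklevel=2,
            )
    return KinematicSeries(
        velocity=vel,
        speed=speed,
        heading=heading,
        valid_mask=valid,
        speed_valid=speed_valid,
        fps=fps,
    )


def _moving_average(pos: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; NaN wherever the window is not fully valid."""
    n = pos.shape[0]
    half = window // 2
    out = np.full_like(pos, np.nan)
    # cumulative-sum trick would propagate NaN anyway, so do it directly
    for k in range(n):
        lo, hi = k - half, k - half + window
        if lo < 0 or hi > n:
            continue
        chunk = pos[lo:hi]
        if np.isfinite(chunk).all():
            out[k] = chunk.mean(axis=0)
    return out
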