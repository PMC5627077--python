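"""Focal-frame alignment maps.

Each fish serves in turn as the *focal* individual: the world is
translated so the focal fish sits at the origin and rotated so it travels
along the positive x-axis.  Partner positions ``(rel_x, rel_y)`` and
heading differences ``delta_theta`` (partner minus focal, wrapped to
(-pi, pi]) are then comparable across frames, fish and trials.  Binning
partners on a relative-position grid gives, per cell, the circular mean
direction of partner motion and the mean resultant length R of the
heading differences — R near 1 means partners at that relative position
travel in nearly the focal fish's direction spread, R near 0 means their
relative headings are dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .io import TrajectorySet
from .kinematics import KinematicSeries
from .pairwise import _check_edges

#: default grid: -100..100 mm in 10 mm cells on both axes
DEFAULT_XY_EDGES = np.arange(-100.0, 101.0, 10.0)


@dataclass
class FocalAlignmentMap:
    """Binned focal-frame surface.

    ``R[i, j]`` is the mean resultant length of the delta_theta values of
    observations with rel_x in ``[x_edges[i], x_edges[i+1])`` and rel_y in
    ``[y_edges[j], y_edges[j+1])``; ``mean_direction`` the corresponding
    circular mean.  Cells with fewer than ``min_count`` observations are
    NaN.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_direction: np.ndarray  # (n_x_bins, n_y_bins), radians
    R: np.ndarray
    count: np.ndarray
    overflow: int
    min_count: int = 10

    def to_dataframe(self) -> pd.DataFrame:
        nx, ny = self.count.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame(
            {
                "x_lo": self.x_edges[xi.ravel()],
                "x_hi": self.x_edges[xi.ravel() + 1],
                "y_lo": self.y_edges[yi.ravel()],
                "y_hi": self.y_edges[yi.ravel() + 1],
                "mean_direction": self.mean_direction.ravel(),
                "R": self.R.ravel(),
                "count": self.count.ravel(),
            }
        )


def focal_transform(k: KinematicSeries, t: TrajectorySet) -> pd.DataFrame:
    """Partner observations in the focal frame, pooled over ordered pairs.

    Columns: focal, partner, frame, rel_x, rel_y, delta_theta.  A pair
    contributes at a frame only when both fish have valid fixes and
    headings.
    """
    theta = np.arctan2(k.heading[..., 1], k.heading[..., 0])
    chunks = []
    n = t.n_individuals
    frames = np.arange(t.n_frames)
    for f in range(n):
        for p in range(n):
            if p == f:
                continue
            ok = (
                k.valid_mask[:, f]
                & k.valid_mask[:, p]
                & ~t.gap_mask[:, f]
                & ~t.gap_mask[:, p]
            )
            if not ok.any():
                continue
            dx = t.positions[ok, p, 0] - t.positions[ok, f, 0]
            dy = t.positions[ok, p, 1] - t.positions[ok, f, 1]
            c, s = np.cos(theta[ok, f]), np.sin(theta[ok, f])
            chunks.append(
                pd.DataFrame(
                    {
                        "focal": f,
                        "partner": p,
                        "frame": frames[ok],
                        "rel_x": c * dx + s * dy,
                        "rel_y": -s * dx + c * dy,
                        "delta_theta": wrap_angle(theta[ok, p] - theta[ok, f]),
                    }
                )
            )
    if not chunks:
        return pd.DataFrame(
            columns=["focal", "partner", "frame", "rel_x", "rel_y", "delta_theta"]
        )
    return pd.concat(chunks, ignore_index=True)


def bin_focal_map(
    obs: pd.DataFrame,
    x_edges=DEFAULT_XY_EDGES,
    y_edges=DEFAULT_XY_EDGES,
    min_count: int = 10,
) -> FocalAlignmentMap:
    """Per-cell circular mean and mean resultant length of delta_theta."""
    x_edges = _check_edges(x_edges, "x_edges")
    y_edges = _check_edges(y_edges, "y_edges")
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    x = obs["rel_x"].to_numpy(dtype=float)
    y = obs["rel_y"].to_numpy(dtype=float)
    th = obs["delta_theta"].to_numpy(dtype=float)
    xi = np.digitize(x, x_edges) - 1
    yi = np.digitize(y, y_edges) - 1
    inside = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
    flat = xi[inside] * ny + yi[inside]
    count = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    csum = np.bincount(flat, weights=np.cos(th[inside]), minlength=nx * ny).reshape(nx, ny)
    ssum = np.bincount(flat, weights=np.sin(th[inside]), minlength=nx * ny).reshape(nx, ny)
    defined = count >= max(min_count, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(defined, np.hypot(csum, ssum) / np.maximum(count, 1), np.nan)
    mean_dir = np.where(defined, np.arctan2(ssum, csum), np.nan)
    return FocalAlignmentMap(
        x_edges=x_edges,
        y_edges=y_edges,
        mean_direction=mean_dir,
        R=R,
        count=count,
        overflow=int(len(th) - inside.sum()),
        min_count=min_count,
    )
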