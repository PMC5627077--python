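"""Pairwise directional correlation binned by mutual speed and distance.

For every unordered pair of fish and every frame where both headings are
valid, the directional correlation ``r`` is the dot product of the two
unit headings (the cosine of the angle between them, in [-1, 1]); the
mutual speed is the arithmetic mean of the two instantaneous speeds and
the distance is the Euclidean separation of the pair.  Averaging r over a
speed x distance grid yields the correlation surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import TrajectorySet
from .kinematics import KinematicSeries

#: default grid: 0-200 mm/s and 0-200 mm in 10-unit steps
DEFAULT_SPEED_EDGES = np.arange(0.0, 201.0, 10.0)
DEFAULT_DISTANCE_EDGES = np.arange(0.0, 201.0, 10.0)


@dataclass
class SpeedDistanceGrid:
    """Binned correlation surface.

    ``mean_r[i, j]`` is the mean directional correlation of observations
    whose mutual speed falls in ``[speed_edges[i], speed_edges[i+1])`` and
    distance in ``[distance_edges[j], distance_edges[j+1])``; NaN where a
    cell holds fewer than ``min_count`` observations.  ``overflow`` counts
    observations falling outside the outermost edges.
    """

    speed_edges: np.ndarray
    distance_edges: np.ndarray
    mean_r: np.ndarray  # (n_speed_bins, n_distance_bins)
    count: np.ndarray
    overflow: int
    min_count: int = 10

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form export: one row per cell."""
        ns, nd = self.count.shape
        si, di = np.meshgrid(np.arange(ns), np.arange(nd), indexing="ij")
        return pd.DataFrame(
            {
                "speed_lo": self.speed_edges[si.ravel()],
                "speed_hi": self.speed_edges[si.ravel() + 1],
                "distance_lo": self.distance_edges[di.ravel()],
                "distance_hi": self.distance_edges[di.ravel() + 1],
                "mean_r": self.mean_r.ravel(),
                "count": self.count.ravel(),
            }
        )


def pair_observations(k: KinematicSeries, t: TrajectorySet) -> pd.DataFrame:
    """One row per unordered pair per frame where both headings are valid.

    Columns: fish_a, fish_b, frame, mutual_speed, distance, r.
    """
    frames = np.arange(t.n_frames)
    chunks = []
    for a, b in combinations(range(t.n_individuals), 2):
        ok = k.valid_mask[:, a] & k.valid_mask[:, b] & ~t.gap_mask[:, a] & ~t.gap_mask[:, b]
        if not ok.any():
            continue
        r = np.einsum("fd,fd->f", k.heading[ok, a], k.heading[ok, b])
        chunks.append(
            pd.DataFrame(
                {
                    "fish_a": a,
                    "fish_b": b,
                    "frame": frames[ok],
                    "mutual_speed": 0.5 * (k.speed[ok, a] + k.speed[ok, b]),
                    "distance": np.linalg.norm(
                        t.positions[ok, a] - t.positions[ok, b], axis=1
                    ),
                    "r": np.clip(r, -1.0, 1.0),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["fish_a", "fish_b", "frame", "mutual_speed", "distance", "r"]
        )
    return pd.concat(chunks, ignore_index=True)


def bin_speed_distance(
    obs: pd.DataFrame,
    speed_edges=DEFAULT_SPEED_EDGES,
    distance_edges=DEFAULT_DISTANCE_EDGES,
    min_count: int = 10,
) -> SpeedDistanceGrid:
    """Average r over half-open speed x distance cells."""
    speed_edges = _check_edges(speed_edges, "speed_edges")
    distance_edges = _check_edges(distance_edges, "distance_edges")
    ns, nd = len(speed_edges) - 1, len(distance_edges) - 1
    s = obs["mutual_speed"].to_numpy(dtype=float)
    d = obs["distance"].to_numpy(dtype=float)
    r = obs["r"].to_numpy(dtype=float)
    si = np.digitize(s, speed_edges) - 1
    di = np.digitize(d, distance_edges) - 1
    inside = (si >= 0) & (si < ns) & (di >= 0) & (di < nd)
    flat = si[inside] * nd + di[inside]
    count = np.bincount(flat, minlength=ns * nd).reshape(ns, nd)
    rsum = np.bincount(flat, weights=r[inside], minlength=ns * nd).reshape(ns, nd)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r = np.where(count >= max(min_count, 1), rsum / np.maximum(count, 1), np.nan)
    return SpeedDistanceGrid(
        speed_edges=speed_edges,
        distance_edges=distance_edges,
        mean_r=mean_r,
        count=count,
        overflow=int(len(r) - inside.sum()),
        min_count=min_count,
    )


def _check_edges(edges, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ConfigError(f"{name} must be a strictly increasing 1-D array")
    return edges
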