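"""Group- and individual-level response variables.

Three response variables are computed per trial and sampling period:

* **mean polarization** (group level): the per-frame polarization is the
  mean resultant length of the valid unit headings,
  ``P = ||sum_i h_i|| / m`` with m the number of valid headings; the
  response is its arithmetic mean over usable frames.  P = 1 means all
  fish move in the same direction; directions that cancel give P = 0.
* **median speed** (per fish, mm/s): the median is used rather than the
  mean because individual speed distributions are positively skewed.
* **mean nearest-neighbour distance** (per fish, mm): per frame, the
  Euclidean distance to the closest other fish with a valid fix, averaged
  over frames where the focal fish and at least one other fish are fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .io import TrajectorySet
from .kinematics import KinematicSeries


@dataclass(frozen=True)
class GroupMetricRecord:
    trial_id: str
    treatment: Optional[str]
    period: Optional[str]
    mean_polarization: float
    n_frames_used: int


@dataclass(frozen=True)
class IndividualMetricRecord:
    trial_id: str
    treatment: Optional[str]
    period: Optional[str]
    fish_id: int
    median_speed: float
    mean_nnd: float


def polarization_timeseries(k: KinematicSeries) -> np.ndarray:
    """Per-frame polarization; NaN for frames with fewer than 2 valid headings."""
    h = np.where(k.valid_mask[..., None], k.heading, 0.0)
    m = k.valid_mask.sum(axis=1)
    resultant = np.linalg.norm(h.sum(axis=1), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m >= 2, resultant / np.maximum(m, 1), np.nan)
    if not np.isfinite(p).any():
        warnings.warn("no frames with >= 2 valid headings", stacklevel=2)
    return p


def mean_polarization(
    series: np.ndarray,
    trial_id: str = "trial",
    treatment: Optional[str] = None,
    period: Optional[str] = None,
) -> GroupMetricRecord:
    """Arithmetic mean of the per-frame polarization over usable frames."""
    series = np.asarray(series, dtype=float)
    usable = np.isfinite(series)
    if not usable.any():
        raise DataError("mean_polarization: no usable frames")
    return GroupMetricRecord(
        trial_id=trial_id,
        treatment=treatment,
        period=period,
        mean_polarization=float(series[usable].mean()),
        n_frames_used=int(usable.sum()),
    )


def nearest_neighbour_distances(t: TrajectorySet) -> np.ndarray:
    """Per-fish per-frame nearest-neighbour distance, shape (frames, fish).

    NaN where the fish has no fix or fewer than 2 fish are fixed in the
    frame.
    """
    pos = np.where(t.gap_mask[..., None], np.nan, t.positions)
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    d = np.linalg.norm(diff, axis=3)  # (frames, fish, fish); NaN via gaps
    n = t.n_individuals
    d[:, np.arange(n), np.arange(n)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        nnd = np.nanmin(d, axis=2)
    return nnd


def mean_nnd(
    t: TrajectorySet,
    trial_id: Optional[str] = None,
) -> np.ndarray:
    """Mean nearest-neighbour distance per fish over usable frames."""
    nnd = nearest_neighbour_distances(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(nnd, axis=0)


def median_speed(k: KinematicSeries, fish_id: int) -> float:
    """Median speed (mm/s) of one fish over frames with defined speed."""
    s = k.speed[:, fish_id]
    valid = k.speed_valid[:, fish_id]
    if not valid.any():
        warnings.warn(f"fish {fish_id}: no valid speeds", stacklevel=2)
        return float("nan")
    return float(np.median(s[valid]))


def metric_records(
    t: TrajectorySet,
    k: KinematicSeries,
    period: Optional[str] = None,
) -> tuple[GroupMetricRecord, list[IndividualMetricRecord]]:
    """Compute all response variables for one trial/window."""
    p = polarization_timeseries(k)
    group = mean_polarization(p, trial_id=t.trial_id, treatment=t.treatment, period=period)
    nnd_means = mean_nnd(t)
    individuals = [
        IndividualMetricRecord(
            trial_id=t.trial_id,
            treatment=t.treatment,
            period=period,
            fish_id=i,
            median_speed=median_speed(k, i),
            mean_nnd=float(nnd_means[i]),
        )
        for i in range(t.n_individuals)
    ]
    return group, individuals


def group_table(records: list[GroupMetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def individual_table(records: list[IndividualMetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
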