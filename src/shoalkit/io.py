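"""Trajectory input/output, calibration, gap handling and windowing.

A trial is a stack of per-frame planar positions for a fixed set of
individually identified fish.  Two on-disk dialects are supported:

* ``tabular_csv`` — the canonical dialect: a CSV with header
  ``frame,id,x,y``, frame indices 0-based, one row per (frame, fish) fix.
  Missing fixes are rows with empty/NaN coordinates (or simply absent
  rows).  Canonical files written by :func:`write_trajectories` are in mm
  (read them back with ``mm_per_unit=1``).
* ``idtracker_text`` — whitespace-separated columns
  ``x1 y1 [prob1] x2 y2 [prob2] ...``, one row per frame, ``NaN`` marking
  missing fixes.  Probability columns, when present, are ignored.

All coordinates are converted to millimetres at read time via
``mm_per_unit``; every downstream computation works in mm and seconds.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigError, ParseError, StructuralError

TREATMENTS = ("familiar", "unfamiliar")
PERIODS = ("period1", "period2")


@dataclass
class TrajectorySet:
    """Calibrated per-frame positions of all individuals in one trial.

    Attributes
    ----------
    positions : ndarray, shape (n_frames, n_individuals, 2)
        Planar positions in mm.  Entries where ``gap_mask`` is True are NaN.
    gap_mask : ndarray of bool, shape (n_frames, n_individuals)
        True where the fix is missing (tracking gap / occlusion).
    fps : float
        Frames per second of the recording.
    mm_per_unit : float
        Calibration that was applied to the raw coordinates.
    """

    positions: np.ndarray
    gap_mask: np.ndarray
    fps: float
    mm_per_unit: float = 1.0
    trial_id: str = "trial"
    treatment: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise StructuralError(
                f"positions must have shape (frames, individuals, 2); "
                f"got {self.positions.shape}"
            )
        if self.gap_mask.shape != self.positions.shape[:2]:
            raise StructuralError("gap_mask shape does not match positions")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.mm_per_unit <= 0:
            raise ConfigError("mm_per_unit must be positive")
        if self.n_individuals < 2:
            raise StructuralError("need at least 2 individuals")
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ConfigError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if not np.all(np.isfinite(self.positions[~self.gap_mask])):
            raise StructuralError("non-finite position at an unmasked fix")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_frames / self.fps


@dataclass(frozen=True)
class SamplingWindow:
    """Half-open frame window ``[start_frame, end_frame)`` of a trial."""

    label: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ConfigError(
                f"window {self.label!r}: start_frame must be < end_frame"
            )
        if self.start_frame < 0:
            raise ConfigError(f"window {self.label!r}: negative start_frame")

    @classmethod
    def from_minutes(cls, label: str, start_min: float, end_min: float, fps: float) -> "SamplingWindow":
        return cls(label, int(round(start_min * 60 * fps)), int(round(end_min * 60 * fps)))

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def default_windows(fps: float = 25.0) -> tuple[SamplingWindow, SamplingWindow]:
    """The study's two 5-minute windows: release (minutes 0-5) and
    habituated (minutes 35-40)."""
    return (
        SamplingWindow.from_minutes("period1", 0.0, 5.0, fps),
        SamplingWindow.from_minutes("period2", 35.0, 40.0, fps),
    )


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def read_trajectories(
    path,
    format: str = "tabular_csv",
    fps: float = 25.0,
    mm_per_unit: float = 1.0,
    trial_id: Optional[str] = None,
    treatment: Optional[str] = None,
    n_individuals: Optional[int] = None,
) -> TrajectorySet:
    """Read a trajectory file and return a calibrated :class:`TrajectorySet`.

    Parameters
    ----------
    format : {"tabular_csv", "idtracker_text"}
        On-disk dialect; see module docstring.
    mm_per_unit : float
        Millimetres per raw coordinate unit; applied at read time.
    n_individuals : int, optional
        For ``idtracker_text`` files without a header row this
        disambiguates 2-column (x y) from 3-column (x y prob) layouts.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if trial_id is None:
        trial_id = path.stem
    if format == "tabular_csv":
        xy, gaps = _read_tabular_csv(path)
    elif format == "idtracker_text":
        xy, gaps = _read_idtracker(path, n_individuals)
    else:
        raise ConfigError(f"unknown trajectory format {format!r}")
    xy = xy * float(mm_per_unit)
    xy[gaps] = np.nan
    return TrajectorySet(
        positions=xy,
        gap_mask=gaps,
        fps=fps,
        mm_per_unit=mm_per_unit,
        trial_id=trial_id,
        treatment=treatment,
    )


def _read_tabular_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(
            path, dtype={"frame": "int64", "id": "int64"}, float_precision="round_trip"
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"frame", "id", "x", "y"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: expected header with columns frame,id,x,y; got {list(df.columns)}"
        )
    for col in ("x", "y"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"  # +1 header +1 one-based
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
    if df.duplicated(subset=["frame", "id"]).any():
        dup = df[df.duplicated(subset=["frame", "id"])].iloc[0]
        raise StructuralError(
            f"{path}: duplicate fix for frame {int(dup['frame'])}, id {int(dup['id'])}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: empty trajectory file")
    if (df["frame"] < 0).any():
        raise ParseError(f"{path}: negative frame index")
    ids = np.sort(df["id"].unique())
    n_frames = int(df["frame"].max()) + 1
    id_index = {fish: k for k, fish in enumerate(ids)}
    xy = np.full((n_frames, len(ids), 2), np.nan)
    rows_f = df["frame"].to_numpy()
    rows_i = df["id"].map(id_index).to_numpy()
    xy[rows_f, rows_i, 0] = df["x"].to_numpy(dtype=float)
    xy[rows_f, rows_i, 1] = df["y"].to_numpy(dtype=float)
    gaps = ~np.isfinite(xy).all(axis=2)
    return xy, gaps


def _read_idtracker(path: Path, n_individuals: Optional[int]) -> tuple[np.ndarray, np.ndarray]:
    rows: list[list[float]] = []
    ncols: Optional[int] = None
    has_prob = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and any(not _is_floatish(f) for f in fields):
                # header row, e.g. "X1 Y1 ProbId1 X2 Y2 ProbId2"
                has_prob = any("prob" in f.lower() for f in fields)
                ncols = len(fields)
                continue
            try:
                vals = [float(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise StructuralError(
                    f"{path}: line {lineno}: expected {ncols} columns, got {len(vals)} "
                    "(inconsistent individual count across frames)"
                )
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: empty trajectory file")
    ncols = len(rows[0])
    if has_prob is None:
        if n_individuals is not None:
            if ncols == 2 * n_individuals:
                has_prob = False
            elif ncols == 3 * n_individuals:
                has_prob = True
            else:
                raise StructuralError(
                    f"{path}: {ncols} columns inconsistent with {n_individuals} individuals"
                )
        else:
            # idTracker's native export carries a ProbId column per fish
            has_prob = ncols % 3 == 0
    stride = 3 if has_prob else 2
    if ncols % stride != 0:
        raise StructuralError(f"{path}: column count {ncols} not divisible by {stride}")
    arr = np.asarray(rows, dtype=float)
    n_fish = ncols // stride
    xy = np.stack([arr[:, stride * k : stride * k + 2] for k in range(n_fish)], axis=1)
    gaps = ~np.isfinite(xy).all(axis=2)
    return xy, gaps


def _is_floatish(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_trajectories(t: TrajectorySet, path) -> None:
    """Write the canonical ``frame,id,x,y`` CSV (coordinates in mm).

    Missing fixes are written with empty coordinate fields so the frame
    count and gap mask round-trip exactly; coordinates use shortest
    round-trip float formatting, so read-back with ``mm_per_unit=1`` is
    bit-exact.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write("frame,id,x,y\n")
    pos, gaps = t.positions, t.gap_mask
    for f in range(t.n_frames):
        for i in range(t.n_individuals):
            if gaps[f, i]:
                buf.write(f"{f},{i},,\n")
            else:
                buf.write(f"{f},{i},{float(pos[f, i, 0])!r},{float(pos[f, i, 1])!r}\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Gap filling and windowing
# ---------------------------------------------------------------------------

def fill_gaps(t: TrajectorySet, max_gap: int = 5) -> TrajectorySet:
    """Linearly interpolate interior runs of missing fixes of length <= max_gap.

    Longer runs, and runs touching the start or end of the trial, stay
    masked.  Measured positions are never altered, so the operation is
    idempotent.  Default of 5 frames = 0.2 s at 25 fps: short occlusions
    only.
    """
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    pos = t.positions.copy()
    gaps = t.gap_mask.copy()
    if max_gap == 0:
        return replace_arrays(t, pos, gaps)
    for i in range(t.n_individuals):
        miss = gaps[:, i]
        if not miss.any() or miss.all():
            continue
        for start, stop in _runs(miss):
            if stop - start > max_gap:
                continue
            if start == 0 or stop == t.n_frames:
                continue  # no anchor on one side
            p0, p1 = pos[start - 1, i], pos[stop, i]
            frac = (np.arange(start, stop) - (start - 1)) / (stop - (start - 1))
            pos[start:stop, i] = p0 + frac[:, None] * (p1 - p0)
            gaps[start:stop, i] = False
    return replace_arrays(t, pos, gaps)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of each True-run in a 1-D boolean mask."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for k in range(0, len(edges), 2):
        yield int(edges[k]), int(edges[k + 1])


def extract_window(t: TrajectorySet, w: SamplingWindow) -> TrajectorySet:
    """Return exactly the frames ``[w.start_frame, w.end_frame)``."""
    if w.end_frame > t.n_frames:
        raise BoundsError(
            f"window {w.label!r} [{w.start_frame}, {w.end_frame}) exceeds "
            f"trial length {t.n_frames} frames"
        )
    return replace_arrays(
        t,
        t.positions[w.start_frame : w.end_frame].copy(),
        t.gap_mask[w.start_frame : w.end_frame].copy(),
    )


def replace_arrays(t: TrajectorySet, positions: np.ndarray, gap_mask: np.ndarray) -> TrajectorySet:
    return TrajectorySet(
        positions=positions,
        gap_mask=gap_mask,
        fps=t.fps,
        mm_per_unit=t.mm_per_unit,
        trial_id=t.trial_id,
        treatment=t.treatment,
    )
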