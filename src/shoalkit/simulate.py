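"""Agent-based shoal simulator in an annular arena.

The generator emulates the study system: four individually identified
fish (body length ~3 cm) swimming in a ring-shaped channel of inner
radius 135 mm and outer radius 330 mm (a 195 mm wide channel), filmed at
25 fps for 5-minute windows.  Agents are kinematic (speed-prescribed)
rather than force-based: the analysis pipeline only needs realistic
positional and heading statistics, not mechanics.

Per time step each fish forms a desired direction as the normalised sum
of

* ``alignment_weight`` x the mean heading of neighbours within
  ``interaction_range``,
* ``attraction_weight`` x the unit vector toward the neighbour centroid,
* ``wall_weight`` x an inward/outward normal that ramps up linearly
  within ``wall_zone`` (20 mm) of either wall,

turns toward it by the fraction ``turn_rate`` of the angular difference,
is perturbed by wrapped-normal heading noise, then advances by a step
drawn from a lognormal speed distribution (speeds are therefore
positively skewed, like real fish).  Positions that would leave the
annulus are reflected radially and the heading's radial component is
reversed.  Fixes are deleted at ``gap_rate`` per frame to mimic tracking
occlusions.  Runs are bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigError
from .io import TrajectorySet, write_trajectories


@dataclass
class SimConfig:
    """Single-trial simulation parameters (mm, seconds, radians)."""

    n_fish: int = 4
    inner_radius: float = 135.0
    outer_radius: float = 330.0
    fps: float = 25.0
    duration: float = 300.0
    alignment_weight: float = 0.5
    attraction_weight: float = 0.5
    wall_weight: float = 1.0
    heading_noise_sd: float = 0.7
    speed_log_mean: float = math.log(60.0)  # lognormal median 60 mm/s
    speed_log_sd: float = 0.45
    interaction_range: float = 200.0
    gap_rate: float = 0.005
    turn_rate: float = 0.4
    wall_zone: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ConfigError(
                f"need 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius}/{self.outer_radius}"
            )
        if self.n_fish < 2:
            raise ConfigError("n_fish must be >= 2")
        if self.fps <= 0 or self.duration <= 0:
            raise ConfigError("fps and duration must be positive")
        for name in ("alignment_weight", "attraction_weight", "wall_weight"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.gap_rate < 1:
            raise ConfigError("gap_rate must be in [0, 1)")
        if not 0 < self.turn_rate <= 1:
            raise ConfigError("turn_rate must be in (0, 1]")
        if self.heading_noise_sd < 0 or self.speed_log_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")


@dataclass
class StudyDesignConfig:
    """Full-study design: groups per treatment and injected effects.

    ``familiarity_alignment_delta`` is added to ``alignment_weight`` for
    familiar groups; ``period2_modifiers`` multiplies the named SimConfig
    parameters for the second sampling window (the key ``speed_median``
    scales the lognormal speed median, i.e. shifts ``speed_log_mean`` by
    its log).  Per-trial seeds are spawned deterministically from the
    master seed.
    """

    n_groups_per_treatment: int = 6
    familiarity_alignment_delta: float = 1.0
    period2_modifiers: dict = field(
        default_factory=lambda: {"alignment_weight": 0.8, "speed_median": 0.85}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups_per_treatment < 1:
            raise ConfigError("n_groups_per_treatment must be >= 1")
        allowed = {
            "alignment_weight",
            "attraction_weight",
            "wall_weight",
            "heading_noise_sd",
            "interaction_range",
            "speed_median",
        }
        bad = set(self.period2_modifiers) - allowed
        if bad:
            raise ConfigError(f"unknown period2_modifiers keys: {sorted(bad)}")


@njit(cache=True)
def _advance(pos0, theta0, steps, noise, inner, outer, w_align, w_attract,
             w_wall, interaction_range, turn_rate, wall_zone):  # pragma: no cover
    n_frames, n_fish = steps.shape
    pos = np.empty((n_frames, n_fish, 2))
    pos[0] = pos0
    theta = theta0.copy()
    for t in range(1, n_frames):
        prev = pos[t - 1]
        for i in range(n_fish):
            # social terms from neighbours within range
            ax = 0.0
            ay = 0.0  # alignment accumulator
            cx = 0.0
            cy = 0.0  # neighbour centroid accumulator
            m = 0
            for j in range(n_fish):
                if j == i:
                    continue
                dx = prev[j, 0] - prev[i, 0]
                dy = prev[j, 1] - prev[i, 1]
                if dx * dx + dy * dy <= interaction_range * interaction_range:
                    ax += math.cos(theta[j])
                    ay += math.sin(theta[j])
                    cx += prev[j, 0]
                    cy += prev[j, 1]
                    m += 1
            dx_des = 0.0
            dy_des = 0.0
            if m > 0:
                na = math.hypot(ax, ay)
                if na > 1e-12:
                    dx_des += w_align * ax / na
                    dy_des += w_align * ay / na
                gx = cx / m - prev[i, 0]
                gy = cy / m - prev[i, 1]
                ng = math.hypot(gx, gy)
                if ng > 1e-12:
                    dx_des += w_attract * gx / ng
                    dy_des += w_attract * gy / ng
            # wall avoidance: inward/outward normal ramping within wall_zone
            r = math.hypot(prev[i, 0], prev[i, 1])
            if r > 1e-12:
                ux = prev[i, 0] / r
                uy = prev[i, 1] / r
                if r > outer - wall_zone:
                    w = (r - (outer - wall_zone)) / wall_zone
                    dx_des -= w_wall * w * ux
                    dy_des -= w_wall * w * uy
                elif r < inner + wall_zone:
                    w = ((inner + wall_zone) - r) / wall_zone
                    dx_des += w_wall * w * ux
                    dy_des += w_wall * w * uy
            nd = math.hypot(dx_des, dy_des)
            if nd > 1e-12:
                desired = math.atan2(dy_des, dx_des)
                delta = desired - theta[i]
                # wrap to (-pi, pi]
                while delta <= -math.pi:
                    delta += 2.0 * math.pi
                while delta > math.pi:
                    delta -= 2.0 * math.pi
                theta[i] += turn_rate * delta
            theta[i] += noise[t, i]
            nx = prev[i, 0] + steps[t, i] * math.cos(theta[i])
            ny = prev[i, 1] + steps[t, i] * math.sin(theta[i])
            # radial reflection at the walls (flips the radial heading
            # component); steps are ~2 mm so a single reflection suffices
            rn = math.hypot(nx, ny)
            if rn > outer or rn < inner:
                if rn > outer:
                    target = 2.0 * outer - rn
                else:
                    target = 2.0 * inner - rn
                if target > outer:
                    target = outer
                elif target < inner:
                    target = inner
                hx = math.cos(theta[i])
                hy = math.sin(theta[i])
                ux = nx / rn
                uy = ny / rn
                dot = hx * ux + hy * uy
                theta[i] = math.atan2(hy - 2.0 * dot * uy, hx - 2.0 * dot * ux)
                nx = ux * target
                ny = uy * target
            pos[t, i, 0] = nx
            pos[t, i, 1] = ny
    return pos


def _initial_state(c: SimConfig, rng: np.random.Generator):
    """Loose shoal at a random spot mid-channel, headed tangentially."""
    mid = 0.5 * (c.inner_radius + c.outer_radius)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    phi = phi0 + rng.uniform(-0.15, 0.15, size=c.n_fish)
    radial_span = 0.3 * (c.outer_radius - c.inner_radius)
    rad = mid + rng.uniform(-radial_span, radial_span, size=c.n_fish)
    pos0 = np.stack([rad * np.cos(phi), rad * np.sin(phi)], axis=1)
    theta0 = phi + np.pi / 2 + rng.normal(0.0, 0.2, size=c.n_fish)
    return pos0, theta0


def simulate_trial(
    c: SimConfig,
    trial_id: str = "sim",
    treatment: Optional[str] = None,
    initial_positions: Optional[np.ndarray] = None,
) -> TrajectorySet:
    """Simulate one trial and return it as a :class:`TrajectorySet`.

    ``initial_positions`` (n_fish, 2), if given, overrides the random
    mid-channel initialisation and must lie inside the annulus.
    """
    c.validate()
    rng = np.random.default_rng(c.seed)
    n_frames = int(round(c.duration * c.fps))
    if n_frames < 3:
        raise ConfigError("duration too short: fewer than 3 frames")
    pos0, theta0 = _initial_state(c, rng)
    if initial_positions is not None:
        pos0 = np.asarray(initial_positions, dtype=float)
        if pos0.shape != (c.n_fish, 2):
            raise ConfigError(f"initial_positions must have shape ({c.n_fish}, 2)")
        radii = np.linalg.norm(pos0, axis=1)
        if np.any(radii < c.inner_radius) or np.any(radii > c.outer_radius):
            raise ConfigError("initial_positions outside the annular channel")
    noise = rng.normal(0.0, c.heading_noise_sd, size=(n_frames, c.n_fish))
    speeds = rng.lognormal(c.speed_log_mean, c.speed_log_sd, size=(n_frames, c.n_fish))
    steps = speeds / c.fps
    pos = _advance(
        pos0,
        np.asarray(theta0, dtype=float),
        steps,
        noise,
        c.inner_radius,
        c.outer_radius,
        c.alignment_weight,
        c.attraction_weight,
        c.wall_weight,
        c.interaction_range,
        c.turn_rate,
        c.wall_zone,
    )
    gap_mask = rng.random((n_frames, c.n_fish)) < c.gap_rate
    pos = pos.copy()
    pos[gap_mask] = np.nan
    return TrajectorySet(
        positions=pos,
        gap_mask=gap_mask,
        fps=c.fps,
        mm_per_unit=1.0,
        trial_id=trial_id,
        treatment=treatment,
    )


def _apply_modifiers(c: SimConfig, modifiers: dict) -> SimConfig:
    changes = {}
    for key, mult in modifiers.items():
        if key == "speed_median":
            changes["speed_log_mean"] = c.speed_log_mean + math.log(mult)
        else:
            changes[key] = getattr(c, key) * mult
    return replace(c, **changes)


def simulate_study(
    d: StudyDesignConfig,
    base: SimConfig,
) -> tuple[list[TrajectorySet], pd.DataFrame]:
    """Simulate the full two-treatment, two-period design.

    Returns one TrajectorySet per trial x period (trial ids ``fam01`` ...
    ``unf06`` by default) plus a metadata table with columns
    (trial_id, treatment, period, seed).  Familiar groups receive
    ``alignment_weight + familiarity_alignment_delta``; period-2 segments
    are generated under ``period2_modifiers``.
    """
    d.validate()
    base.validate()
    ss = np.random.SeedSequence(d.seed)
    n_trials = 2 * d.n_groups_per_treatment
    children = ss.spawn(2 * n_trials)  # one stream per trial x period
    trials: list[TrajectorySet] = []
    meta_rows = []
    idx = 0
    for treatment in ("familiar", "unfamiliar"):
        cfg_t = base
        if treatment == "familiar":
            cfg_t = replace(
                base, alignment_weight=base.alignment_weight + d.familiarity_alignment_delta
            )
        for g in range(d.n_groups_per_treatment):
            trial_id = f"{treatment[:3]}{g + 1:02d}"
            for period in ("period1", "period2"):
                cfg = cfg_t if period == "period1" else _apply_modifiers(
                    cfg_t, d.period2_modifiers
                )
                seed = int(children[idx].generate_state(1)[0] % (2**31))
                idx += 1
                traj = simulate_trial(
                    replace(cfg, seed=seed), trial_id=trial_id, treatment=treatment
                )
                trials.append(traj)
                meta_rows.append(
                    {
                        "trial_id": trial_id,
                        "treatment": treatment,
                        "period": period,
                        "seed": seed,
                    }
                )
    return trials, pd.DataFrame(meta_rows)


def write_study(trials: list[TrajectorySet], metadata: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write each segment as canonical CSV plus a metadata.csv manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = metadata.copy()
    files = []
    for traj, (_, row) in zip(trials, meta.iterrows()):
        fname = f"{row['trial_id']}_{row['period']}.csv"
        write_trajectories(traj, outdir / fname)
        files.append(fname)
    meta["file"] = files
    meta.to_csv(outdir / "metadata.csv", index=False)
    return meta
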