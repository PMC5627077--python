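"""End-to-end orchestration: simulate -> analyse -> infer -> export.

Every run is a pure function of (inputs, config, seed): re-running with
the same configuration reproduces the CSV outputs byte for byte.  Each
stage writes its outputs under the run's output directory and records
them in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import focal, inference, metrics, pairwise, simulate, viz
from .errors import ConfigError, DataError, ShoalkitError
from .io import (
    SamplingWindow,
    TrajectorySet,
    extract_window,
    fill_gaps,
    read_trajectories,
)
from .kinematics import compute_kinematics

log = logging.getLogger("shoalkit")


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable)."""

    outdir: str = "shoalkit_run"
    seed: int = 0
    # simulation
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    design: dict = field(default_factory=dict)  # StudyDesignConfig overrides
    # analysis inputs
    input_dir: Optional[str] = None
    format: str = "tabular_csv"
    fps: float = 25.0
    mm_per_unit: float = 1.0
    max_gap: int = 5
    windows: dict = field(
        default_factory=lambda: {"period1": [0.0, 5.0], "period2": [35.0, 40.0]}
    )
    # kinematics
    diff_method: str = "central"
    min_heading_speed: float = 1.0
    smooth_window: int = 0
    # binning
    speed_max: float = 200.0
    speed_step: float = 10.0
    distance_max: float = 200.0
    distance_step: float = 10.0
    xy_max: float = 100.0
    xy_step: float = 10.0
    min_cell_count: int = 10
    # outputs
    make_figures: bool = True
    fdr_q: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sampling_windows(self) -> list[SamplingWindow]:
        wins = [
            SamplingWindow.from_minutes(label, lo, hi, self.fps)
            for label, (lo, hi) in sorted(self.windows.items())
        ]
        for a, b in zip(wins, wins[1:]):
            if b.start_frame < a.end_frame:
                raise ConfigError(f"windows {a.label!r} and {b.label!r} overlap")
        return wins


def _setup_logging(cfg: RunConfig, outdir: Path) -> None:
    level = getattr(logging, cfg.log_level.upper(), logging.INFO)
    log.setLevel(level)
    log.handlers = [
        logging.StreamHandler(),
        logging.FileHandler(outdir / "run.log", mode="a"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def _edges(maximum: float, step: float) -> np.ndarray:
    return np.arange(0.0, maximum + step / 2, step)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulation(cfg: RunConfig) -> pd.DataFrame:
    """Simulate the study design and write trajectory CSVs + metadata."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)
    base = simulate.SimConfig(**cfg.sim)
    design = simulate.StudyDesignConfig(**{"seed": cfg.seed, **cfg.design})
    base.validate()
    design.validate()
    log.info(
        "simulating %d trials x 2 periods (%.0f s at %.0f fps)",
        2 * design.n_groups_per_treatment,
        base.duration,
        base.fps,
    )
    trials, meta = simulate.simulate_study(design, base)
    traj_dir = outdir / "trajectories"
    meta = simulate.write_study(trials, meta, traj_dir)
    _append_manifest(outdir, [f"trajectories/{f}" for f in meta["file"]] + ["trajectories/metadata.csv"])
    log.info("wrote %d trajectory files to %s", len(meta), traj_dir)
    return meta


def _load_segments(cfg: RunConfig) -> list[tuple[TrajectorySet, str]]:
    """Yield (trajectory, period) pairs from the input directory.

    If metadata.csv carries a ``period`` column the files are taken as
    pre-cut segments; otherwise each file is a full trial and the
    configured windows are applied.
    """
    if cfg.input_dir is None:
        raise ConfigError("analysis requires input_dir")
    indir = Path(cfg.input_dir)
    meta_path = indir / "metadata.csv"
    if not meta_path.exists():
        raise DataError(f"missing metadata file: {meta_path}")
    meta = pd.read_csv(meta_path)
    for col in ("trial_id", "treatment", "file"):
        if col not in meta.columns:
            raise DataError(f"{meta_path}: missing column {col!r}")
    segments = []
    for _, row in meta.iterrows():
        path = indir / row["file"]
        if not path.exists():
            raise DataError(f"trial {row['trial_id']}: missing input file {path}")
        traj = read_trajectories(
            path,
            format=cfg.format,
            fps=cfg.fps,
            mm_per_unit=cfg.mm_per_unit,
            trial_id=str(row["trial_id"]),
            treatment=str(row["treatment"]),
        )
        traj = fill_gaps(traj, cfg.max_gap)
        if "period" in meta.columns and isinstance(row["period"], str):
            segments.append((traj, row["period"]))
        else:
            for w in cfg.sampling_windows():
                segments.append((extract_window(traj, w), w.label))
    return segments


def run_analysis(cfg: RunConfig) -> dict:
    """Compute metric tables, correlation grids, focal maps and model fits."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)
    segments = _load_segments(cfg)
    log.info("analysing %d trial segments", len(segments))

    group_records, indiv_records = [], []
    pooled_pairs: dict[tuple[str, str], list[pd.DataFrame]] = {}
    pooled_focal: dict[tuple[str, str], list[pd.DataFrame]] = {}
    for traj, period in segments:
        try:
            k = compute_kinematics(
                traj,
                method=cfg.diff_method,
                min_heading_speed=cfg.min_heading_speed,
                smooth_window=cfg.smooth_window,
            )
            g, ind = metrics.metric_records(traj, k, period=period)
        except ShoalkitError as exc:
            raise type(exc)(f"stage=metrics trial={traj.trial_id} period={period}: {exc}") from exc
        group_records.append(g)
        indiv_records.extend(ind)
        key = (traj.treatment or "all", period)
        pooled_pairs.setdefault(key, []).append(pairwise.pair_observations(k, traj))
        pooled_focal.setdefault(key, []).append(focal.focal_transform(k, traj))

    outputs = []
    metrics_dir = outdir / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    gdf = metrics.group_table(group_records)
    idf = metrics.individual_table(indiv_records)
    gdf.to_csv(metrics_dir / "group_metrics.csv", index=False)
    idf.to_csv(metrics_dir / "individual_metrics.csv", index=False)
    outputs += ["metrics/group_metrics.csv", "metrics/individual_metrics.csv"]

    speed_edges = _edges(cfg.speed_max, cfg.speed_step)
    distance_edges = _edges(cfg.distance_max, cfg.distance_step)
    xy_edges = np.arange(-cfg.xy_max, cfg.xy_max + cfg.xy_step / 2, cfg.xy_step)
    surf_dir = outdir / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    fig_dir = outdir / "figures"
    if cfg.make_figures:
        fig_dir.mkdir(exist_ok=True)
    for (treatment, period), chunks in sorted(pooled_pairs.items()):
        obs = pd.concat(chunks, ignore_index=True)
        grid = pairwise.bin_speed_distance(
            obs, speed_edges, distance_edges, min_count=cfg.min_cell_count
        )
        name = f"pair_correlation_{treatment}_{period}"
        grid.to_dataframe().to_csv(surf_dir / f"{name}.csv", index=False)
        outputs.append(f"surfaces/{name}.csv")
        if cfg.make_figures:
            fig = viz.plot_speed_distance_grid(grid, title=f"{treatment} {period}")
            fig.savefig(fig_dir / f"{name}.png", dpi=120)
            outputs.append(f"figures/{name}.png")
    for (treatment, period), chunks in sorted(pooled_focal.items()):
        obs = pd.concat(chunks, ignore_index=True)
        fmap = focal.bin_focal_map(obs, xy_edges, xy_edges, min_count=cfg.min_cell_count)
        name = f"focal_alignment_{treatment}_{period}"
        fmap.to_dataframe().to_csv(surf_dir / f"{name}.csv", index=False)
        outputs.append(f"surfaces/{name}.csv")
        if cfg.make_figures:
            fig = viz.plot_focal_map(fmap, title=f"{treatment} {period}")
            fig.savefig(fig_dir / f"{name}.png", dpi=120)
            outputs.append(f"figures/{name}.png")

    infer_outputs = run_inference(cfg, metrics_dir=metrics_dir)
    outputs += infer_outputs
    _append_manifest(outdir, outputs)
    log.info("analysis complete: %d outputs", len(outputs))
    return {
        "group_metrics": gdf,
        "individual_metrics": idf,
        "outputs": outputs,
    }


def run_inference(cfg: RunConfig, metrics_dir=None) -> list[str]:
    """Fit the three repeated-measures models and apply BH FDR."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics_dir = Path(metrics_dir) if metrics_dir else outdir / "metrics"
    gpath = metrics_dir / "group_metrics.csv"
    ipath = metrics_dir / "individual_metrics.csv"
    for p in (gpath, ipath):
        if not p.exists():
            raise DataError(f"missing metrics table: {p}")
    gdf = pd.read_csv(gpath)
    idf = pd.read_csv(ipath)
    fits = []
    fits += inference.fit_group_model(gdf)
    fits += inference.fit_individual_model(idf, "log_speed")
    fits += inference.fit_individual_model(idf, "log_nnd")
    table = inference.fits_table(fits)
    infer_dir = outdir / "inference"
    infer_dir.mkdir(exist_ok=True)
    table.to_csv(infer_dir / "model_fits.csv", index=False)
    tests = table[table["term"] != "intercept"].reset_index(drop=True)
    fdr = inference.benjamini_hochberg(tests["p_value"].to_numpy(), q=cfg.fdr_q)
    tests = tests.assign(bh_adjusted_p=fdr.adjusted, significant=fdr.significant)
    tests.to_csv(infer_dir / "fdr.csv", index=False)
    outputs = ["inference/model_fits.csv", "inference/fdr.csv"]
    diag_rows = []
    for resp, frame, col in (
        ("mean_polarization", gdf, "mean_polarization"),
        ("log_speed", idf.assign(v=np.log(idf["median_speed"])), "v"),
        ("log_nnd", idf.assign(v=np.log(idf["mean_nnd"])), "v"),
    ):
        try:
            diag = inference.assumption_checks(frame, col)
        except DataError as exc:
            log.warning("skipping diagnostics for %s: %s", resp, exc)
            continue
        sub = diag["shapiro"].assign(
            response=resp,
            levene_stat=diag["levene"]["statistic"],
            levene_p=diag["levene"]["p_value"],
        )
        diag_rows.append(sub)
        diag["qq"].to_csv(infer_dir / f"qq_{resp}.csv", index=False)
        outputs.append(f"inference/qq_{resp}.csv")
    if diag_rows:
        pd.concat(diag_rows, ignore_index=True).to_csv(
            infer_dir / "diagnostics.csv", index=False
        )
        outputs.append("inference/diagnostics.csv")
    return outputs


def study_metric_tables(
    design: simulate.StudyDesignConfig,
    base: simulate.SimConfig,
    diff_method: str = "central",
    min_heading_speed: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a study and compute the metric tables in memory.

    Convenience path (no file round-trip) for replicate experiments:
    returns the group-level and individual-level metric tables ready for
    :func:`shoalkit.inference.fit_group_model` /
    :func:`~shoalkit.inference.fit_individual_model`.
    """
    trials, meta = simulate.simulate_study(design, base)
    group_records, indiv_records = [], []
    for traj, (_, row) in zip(trials, meta.iterrows()):
        k = compute_kinematics(traj, method=diff_method, min_heading_speed=min_heading_speed)
        g, ind = metrics.metric_records(traj, k, period=row["period"])
        group_records.append(g)
        indiv_records.extend(ind)
    return metrics.group_table(group_records), metrics.individual_table(indiv_records)


def run_all(cfg: RunConfig) -> dict:
    """simulate -> analyse -> infer in one go."""
    run_simulation(cfg)
    cfg = dataclasses.replace(cfg, input_dir=str(Path(cfg.outdir) / "trajectories"))
    return run_analysis(cfg)


def _append_manifest(outdir: Path, outputs: list[str]) -> None:
    manifest_path = outdir / "manifest.json"
    existing = []
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
    merged = list(dict.fromkeys(existing + list(outputs)))
    manifest_path.write_text(json.dumps(merged, indent=1) + "\n")
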