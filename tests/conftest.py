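import numpy as np
import pandas as pd
import pytest

from shoalkit.io import TrajectorySet
from shoalkit.simulate import SimConfig, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def line_trajectory():
    """4 fish in a line at x = 0, 10, 20, 30 mm, moving +x at 10 mm/frame."""
    n_frames = 20
    x0 = np.array([0.0, 10.0, 20.0, 30.0])
    pos = np.zeros((n_frames, 4, 2))
    pos[:, :, 0] = x0[None, :] + 10.0 * np.arange(n_frames)[:, None]
    return TrajectorySet(
        positions=pos,
        gap_mask=np.zeros((n_frames, 4), dtype=bool),
        fps=25.0,
        trial_id="line",
    )


@pytest.fixture(scope="session")
def sim_trajectory():
    """One minute of default-parameter simulation (compiled once per session)."""
    return simulate_trial(SimConfig(duration=60.0, seed=11), trial_id="sim11")


def make_metric_tables(
    rng,
    n_groups_per_treatment=6,
    fam_effect=0.08,
    time_effect=-0.05,
    interaction=-0.03,
    group_sd=0.04,
    resid_sd=0.03,
):
    """Synthetic balanced split-plot tables matching the study design."""
    group_rows, indiv_rows = [], []
    for g in range(2 * n_groups_per_treatment):
        treat = "familiar" if g < n_groups_per_treatment else "unfamiliar"
        fam = 1.0 if treat == "familiar" else 0.0
        u = rng.normal(0, group_sd)
        for per, x in (("period1", 0.0), ("period2", 1.0)):
            y = 0.75 + fam_effect * fam + time_effect * x + interaction * fam * x
            y += u + rng.normal(0, resid_sd)
            group_rows.append(
                dict(trial_id=f"g{g:02d}", treatment=treat, period=per, mean_polarization=y)
            )
        for f in range(4):
            v = rng.normal(0, 0.15)
            for per, x in (("period1", 0.0), ("period2", 1.0)):
                mu = 4.0 + 0.2 * fam - 0.3 * x + u + v + rng.normal(0, 0.1)
                nu = 3.5 - 0.1 * fam + 0.1 * x + u + v + rng.normal(0, 0.1)
                indiv_rows.append(
                    dict(
                        trial_id=f"g{g:02d}",
                        treatment=treat,
                        period=per,
                        fish_id=f,
                        median_speed=float(np.exp(mu)),
                        mean_nnd=float(np.exp(nu)),
                    )
                )
    return pd.DataFrame(group_rows), pd.DataFrame(indiv_rows)


@pytest.fixture
def metric_tables(rng):
    return make_metric_tables(rng)
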