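import numpy as np
import pandas as pd
import pytest

from shoalkit.circular import circular_mean, resultant_length, wrap_angle
from shoalkit.errors import ConfigError
from shoalkit.focal import bin_focal_map, focal_transform
from shoalkit.io import TrajectorySet, replace_arrays
from shoalkit.kinematics import KinematicSeries, compute_kinematics
from shoalkit.metrics import polarization_timeseries


def pair_series(focal_angle, partner_angle, focal_pos, partner_pos):
    angles = np.array([[focal_angle, partner_angle]] * 3)
    heading = np.stack([np.cos(angles), np.sin(angles)], axis=2)
    k = KinematicSeries(
        velocity=heading * 50.0,
        speed=np.full((3, 2), 50.0),
        heading=heading,
        valid_mask=np.ones((3, 2), bool),
        speed_valid=np.ones((3, 2), bool),
        fps=25.0,
    )
    pos = np.array([[focal_pos, partner_pos]] * 3, dtype=float)
    t = TrajectorySet(positions=pos, gap_mask=np.zeros((3, 2), bool), fps=25.0)
    return k, t


class TestFocalTransform:
    def test_identity_rotation(self):
        k, t = pair_series(0.0, 0.0, (0, 0), (10, 0))
        obs = focal_transform(k, t)
        front = obs[(obs["focal"] == 0)]
        assert front["rel_x"].to_numpy() == pytest.approx(10.0)
        assert front["rel_y"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert front["delta_theta"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_focal_frame(self):
        # focal at origin heading +y; partner straight ahead at absolute (0, 10)
        k, t = pair_series(np.pi / 2, np.pi / 2, (0, 0), (0, 10))
        obs = focal_transform(k, t)
        front = obs[(obs["focal"] == 0)]
        assert front["rel_x"].to_numpy() == pytest.approx(10.0)
        assert front["rel_y"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert front["delta_theta"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_antialigned_partner_behind(self):
        k, t = pair_series(0.0, np.pi, (0, 0), (-5, 0))
        obs = focal_transform(k, t)
        front = obs[(obs["focal"] == 0)]
        assert front["rel_x"].to_numpy() == pytest.approx(-5.0)
        assert front["delta_theta"].to_numpy() == pytest.approx(np.pi)

    def test_ordered_pairs_pooled(self, sim_trajectory):
        k = compute_kinematics(sim_trajectory)
        obs = focal_transform(k, sim_trajectory)
        n = sim_trajectory.n_individuals
        pairs = set(map(tuple, obs[["focal", "partner"]].drop_duplicates().to_numpy()))
        assert len(pairs) == n * (n - 1)

    def test_world_rotation_leaves_observations_unchanged(self, sim_trajectory):
        phi = 0.8
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        rot = replace_arrays(sim_trajectory, sim_trajectory.positions @ R.T, sim_trajectory.gap_mask)
        a = focal_transform(compute_kinematics(sim_trajectory), sim_trajectory)
        b = focal_transform(compute_kinematics(rot), rot)
        assert len(a) == len(b)
        for col in ("rel_x", "rel_y"):
            assert np.allclose(a[col], b[col], atol=1e-9)
        dd = wrap_angle(a["delta_theta"].to_numpy() - b["delta_theta"].to_numpy())
        assert np.allclose(dd, 0.0, atol=1e-9)


def obs_frame(x, y, theta):
    return pd.DataFrame({"rel_x": x, "rel_y": y, "delta_theta": theta})


class TestBinFocalMap:
    def test_aligned_cell(self):
        obs = obs_frame([5.0] * 3, [5.0] * 3, [0.0] * 3)
        m = bin_focal_map(obs, [0, 10], [0, 10], min_count=1)
        assert m.R[0, 0] == pytest.approx(1.0)
        assert m.mean_direction[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_cancelling_cell(self):
        obs = obs_frame([5.0, 5.0], [5.0, 5.0], [0.0, np.pi])
        m = bin_focal_map(obs, [0, 10], [0, 10], min_count=1)
        assert m.R[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_unit_vector_sum_oracle(self, rng):
        obs = obs_frame(
            rng.uniform(-100, 100, 2000),
            rng.uniform(-100, 100, 2000),
            rng.uniform(-np.pi, np.pi, 2000),
        )
        edges = np.arange(-100, 101, 50.0)
        m = bin_focal_map(obs, edges, edges, min_count=1)
        for i in range(len(edges) - 1):
            for j in range(len(edges) - 1):
                sel = (
                    (obs["rel_x"] >= edges[i])
                    & (obs["rel_x"] < edges[i + 1])
                    & (obs["rel_y"] >= edges[j])
                    & (obs["rel_y"] < edges[j + 1])
                )
                if not sel.any():
                    continue
                th = obs.loc[sel, "delta_theta"].to_numpy()
                assert m.R[i, j] == pytest.approx(resultant_length(th), abs=1e-12)
                assert wrap_angle(m.mean_direction[i, j] - circular_mean(th)) == pytest.approx(
                    0.0, abs=1e-12
                )

    def test_cell_R_equals_polarization_of_cell_angles(self, rng):
        """Cross-module consistency: R is the polarization of the cell's angles."""
        from shoalkit.kinematics import KinematicSeries

        th = rng.uniform(-np.pi, np.pi, 64)
        obs = obs_frame(np.full(64, 5.0), np.full(64, 5.0), th)
        m = bin_focal_map(obs, [0, 10], [0, 10], min_count=1)
        heading = np.stack([np.cos(th), np.sin(th)], axis=1)[None]
        k = KinematicSeries(
            velocity=heading * 10,
            speed=np.full((1, 64), 10.0),
            heading=heading,
            valid_mask=np.ones((1, 64), bool),
            speed_valid=np.ones((1, 64), bool),
            fps=25.0,
        )
        p = polarization_timeseries(k)
        assert m.R[0, 0] == pytest.approx(p[0], abs=1e-12)

    def test_mass_conservation_and_min_count(self, rng):
        obs = obs_frame(
            rng.uniform(-150, 150, 500),
            rng.uniform(-150, 150, 500),
            rng.uniform(-np.pi, np.pi, 500),
        )
        m = bin_focal_map(obs)
        assert m.count.sum() + m.overflow == len(obs)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ConfigError):
            bin_focal_map(obs_frame([0.0], [0.0], [0.0]), [0, -10], [0, 10])


def test_map_invariant_under_world_rotation(sim_trajectory):
    phi = 2.1
    c, s = np.cos(phi), np.sin(phi)
    R = np.array([[c, -s], [s, c]])
    rot = replace_arrays(sim_trajectory, sim_trajectory.positions @ R.T, sim_trajectory.gap_mask)
    edges = np.arange(-100, 101, 20.0)
    m0 = bin_focal_map(focal_transform(compute_kinematics(sim_trajectory), sim_trajectory), edges, edges)
    m1 = bin_focal_map(focal_transform(compute_kinematics(rot), rot), edges, edges)
    assert np.array_equal(m0.count, m1.count)
    ok = np.isfinite(m0.R)
    assert np.allclose(m0.R[ok], m1.R[ok], atol=1e-9)
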