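import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from shoalkit.errors import ConfigError, DataError
from shoalkit.inference import (
    assumption_checks,
    benjamini_hochberg,
    fit_group_model,
    fit_individual_model,
    fits_table,
)
from conftest import make_metric_tables

#: p-values of the nine fixed-effect tests (three terms for each of the
#: three responses) reported by the guppy familiarity study; "<0.001" is
#: encoded as 0.0005 (the BH outcome is insensitive to any value <= 0.001).
STUDY_P_VALUES = (0.007, 0.057, 0.096, 0.023, 0.0005, 0.021, 0.164, 0.035, 0.235)


class TestGroupModel:
    def test_balanced_design_df_and_terms(self, metric_tables):
        gdf, _ = metric_tables
        fits = fits_table(fit_group_model(gdf))
        fam = fits[fits["term"] == "familiarity"].iloc[0]
        tim = fits[fits["term"] == "time"].iloc[0]
        # containment df: 12 groups, 2 between-subject parameters
        assert fam["df"] == 10
        assert tim["df"] == 10
        assert set(fits["term"]) == {"intercept", "familiarity", "time", "fam_x_time"}
        assert (fits["std_error"] > 0).all()
        assert fits["p_value"].between(0, 1).all()

    def test_known_effect_recovered_within_2se(self, rng):
        gdf, _ = make_metric_tables(rng, fam_effect=0.08)
        fam = fits_table(fit_group_model(gdf)).set_index("term").loc["familiarity"]
        assert abs(fam["estimate"] - 0.08) < 2 * fam["std_error"]

    def test_constant_shift_moves_only_intercept(self, metric_tables):
        gdf, _ = metric_tables
        a = fits_table(fit_group_model(gdf)).set_index("term")
        shifted = gdf.assign(mean_polarization=gdf["mean_polarization"] + 0.1)
        b = fits_table(fit_group_model(shifted)).set_index("term")
        assert b.loc["intercept", "estimate"] == pytest.approx(
            a.loc["intercept", "estimate"] + 0.1, abs=1e-6
        )
        for term in ("familiarity", "time", "fam_x_time"):
            assert b.loc[term, "estimate"] == pytest.approx(a.loc[term, "estimate"], abs=1e-6)

    def test_relabelling_invariance(self, metric_tables, rng):
        gdf, _ = metric_tables
        mapping = {t: f"renamed_{k}" for k, t in enumerate(rng.permutation(gdf["trial_id"].unique()))}
        relabelled = gdf.assign(trial_id=gdf["trial_id"].map(mapping))
        a = fits_table(fit_group_model(gdf)).set_index("term")["estimate"]
        b = fits_table(fit_group_model(relabelled)).set_index("term")["estimate"]
        assert np.allclose(a, b, atol=1e-8)

    def test_missing_cell_raises_with_location(self, metric_tables):
        gdf, _ = metric_tables
        broken = gdf.drop(gdf.index[3])
        with pytest.raises(DataError, match="period2"):
            fit_group_model(broken)


class TestIndividualModel:
    def test_constant_response_gives_zero_effects(self, metric_tables):
        _, idf = metric_tables
        const = idf.assign(median_speed=50.0)
        fits = fits_table(fit_individual_model(const, "log_speed")).set_index("term")
        for term in ("familiarity", "time", "fam_x_time"):
            assert fits.loc[term, "estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_containment_dfs_match_design(self, metric_tables):
        _, idf = metric_tables
        fits = fits_table(fit_individual_model(idf, "log_speed")).set_index("term")
        # 12 groups -> between df 10; 96 obs, 48 fish, 2 within params -> 46
        assert fits.loc["familiarity", "df"] == 10
        assert fits.loc["time", "df"] == 46
        assert fits.loc["fam_x_time", "df"] == 46

    def test_known_time_effect_recovered(self, rng):
        _, idf = make_metric_tables(rng)  # log-speed time effect -0.3
        tim = fits_table(fit_individual_model(idf, "log_speed")).set_index("term").loc["time"]
        assert abs(tim["estimate"] - (-0.3)) < 2 * tim["std_error"]

    def test_nonpositive_values_rejected_with_location(self, metric_tables):
        _, idf = metric_tables
        bad = idf.copy()
        bad.loc[bad.index[5], "mean_nnd"] = -1.0
        with pytest.raises(DataError, match="mean_nnd"):
            fit_individual_model(bad, "log_nnd")

    def test_unknown_response_rejected(self, metric_tables):
        _, idf = metric_tables
        with pytest.raises(ConfigError):
            fit_individual_model(idf, "speed")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestAgainstNlme:
    """Independent oracle: nlme::lme (REML, containment df) on the same data."""

    def _run_r(self, script, tmp_path):
        rfile = tmp_path / "check.R"
        rfile.write_text(script)
        out = subprocess.run(
            ["Rscript", str(rfile)], capture_output=True, text=True, check=True
        )
        return pd.read_csv(tmp_path / "ttable.csv")

    def test_group_model_matches_lme(self, metric_tables, tmp_path):
        gdf, _ = metric_tables
        gdf.to_csv(tmp_path / "g.csv", index=False)
        ttable = self._run_r(
            textwrap.dedent(
                f"""
                suppressMessages(library(nlme))
                g <- read.csv("{tmp_path}/g.csv")
                g$fam <- as.numeric(g$treatment == "familiar")
                g$tim <- as.numeric(g$period == "period2")
                m <- lme(mean_polarization ~ fam + tim + fam:tim,
                         random = ~1 | trial_id, data = g, method = "REML")
                write.csv(summary(m)$tTable, "{tmp_path}/ttable.csv")
                """
            ),
            tmp_path,
        )
        ours = fits_table(fit_group_model(gdf))
        r_order = ["(Intercept)", "fam", "tim", "fam:tim"]
        ref = ttable.set_index(ttable.columns[0]).loc[r_order]
        assert np.allclose(ours["estimate"], ref["Value"], atol=1e-5)
        assert np.allclose(ours["std_error"], ref["Std.Error"], rtol=1e-3)
        assert np.array_equal(ours["df"], ref["DF"])
        assert np.allclose(ours["t_value"], ref["t-value"], rtol=1e-3)

    def test_individual_model_matches_lme(self, metric_tables, tmp_path):
        _, idf = metric_tables
        idf.to_csv(tmp_path / "i.csv", index=False)
        ttable = self._run_r(
            textwrap.dedent(
                f"""
                suppressMessages(library(nlme))
                i <- read.csv("{tmp_path}/i.csv")
                i$fam <- as.numeric(i$treatment == "familiar")
                i$tim <- as.numeric(i$period == "period2")
                m <- lme(log(median_speed) ~ fam + tim + fam:tim,
                         random = ~1 | trial_id/fish_id, data = i, method = "REML")
                write.csv(summary(m)$tTable, "{tmp_path}/ttable.csv")
                """
            ),
            tmp_path,
        )
        ours = fits_table(fit_individual_model(idf, "log_speed"))
        r_order = ["(Intercept)", "fam", "tim", "fam:tim"]
        ref = ttable.set_index(ttable.columns[0]).loc[r_order]
        assert np.allclose(ours["estimate"], ref["Value"], atol=1e-4)
        assert np.allclose(ours["std_error"], ref["Std.Error"], rtol=1e-3)
        assert np.array_equal(ours["df"], ref["DF"])


class TestAssumptionChecks:
    def test_normal_sample_passes_shapiro_at_nominal_rate(self, rng):
        """Shapiro rejects a truly normal sample in ~5% of draws."""
        passed = 0
        for _ in range(60):
            df = pd.DataFrame(
                {
                    "treatment": "familiar",
                    "period": "period1",
                    "v": rng.normal(size=500),
                }
            )
            diag = assumption_checks(df, "v")
            passed += int(diag["shapiro"]["shapiro_p"].iloc[0] > 0.05)
        assert 0.85 <= passed / 60 <= 1.0

    def test_lognormal_sample_fails_shapiro(self, rng):
        """Strong right skew is detected essentially always at n=100."""
        for _ in range(20):
            df = pd.DataFrame(
                {
                    "treatment": "familiar",
                    "period": "period1",
                    "v": rng.lognormal(0, 1, size=100),
                }
            )
            diag = assumption_checks(df, "v")
            assert (diag["shapiro"]["shapiro_p"] < 0.05).all()

    def test_equal_variances_give_small_levene(self, rng):
        base = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "treatment": ["familiar"] * 50 + ["unfamiliar"] * 50,
                "period": "period1",
                "v": np.concatenate([base, base + 5.0]),  # same spread, shifted
            }
        )
        diag = assumption_checks(df, "v")
        assert diag["levene"]["statistic"] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_cell_flagged_not_fatal(self):
        df = pd.DataFrame(
            {
                "treatment": ["familiar"] * 3 + ["unfamiliar"] * 3,
                "period": "period1",
                "v": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
            }
        )
        diag = assumption_checks(df, "v")
        assert diag["shapiro"]["degenerate"].any()

    def test_qq_data_exported(self, rng):
        df = pd.DataFrame(
            {"treatment": "familiar", "period": "period1", "v": rng.normal(size=30)}
        )
        diag = assumption_checks(df, "v")
        assert len(diag["qq"]) == 30
        assert diag["qq"]["sample"].is_monotonic_increasing


class TestBenjaminiHochberg:
    def test_study_p_values_mark_exactly_two(self):
        res = benjamini_hochberg(STUDY_P_VALUES, q=0.05)
        assert res.n_significant == 2
        flagged = set(np.asarray(STUDY_P_VALUES)[res.significant])
        assert flagged == {0.0005, 0.007}

    def test_insensitive_to_encoding_of_very_small_p(self):
        for tiny in (1e-6, 0.0005, 0.001):
            ps = list(STUDY_P_VALUES)
            ps[4] = tiny
            assert benjamini_hochberg(ps, q=0.05).n_significant == 2

    def test_all_ones_none_significant(self):
        res = benjamini_hochberg([1.0] * 5)
        assert res.n_significant == 0

    def test_single_small_p_significant(self):
        assert benjamini_hochberg([0.04], q=0.05).significant[0]

    def test_prefix_property(self, rng):
        p = rng.uniform(size=40)
        res = benjamini_hochberg(p, q=0.1)
        order = np.argsort(p)
        sig_sorted = res.significant[order]
        assert not np.any(~sig_sorted[: res.n_significant])
        assert not sig_sorted[res.n_significant :].any()

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=20)
        before = benjamini_hochberg(p, q=0.05).significant.sum()
        p2 = p.copy()
        p2[np.argmax(p)] = 0.001
        after = benjamini_hochberg(p2, q=0.05).significant.sum()
        assert after >= before

    def test_matches_statsmodels(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 30))
            res = benjamini_hochberg(p, q=0.05)
            ref_sig, ref_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(res.significant, ref_sig)
            assert np.allclose(res.adjusted, ref_adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            benjamini_hochberg([0.5, 1.5])
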