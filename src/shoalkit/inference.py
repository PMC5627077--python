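"""Repeated-measures inference on the shoal metrics.

The design is a classic split-plot: treatment (familiar vs unfamiliar
groups) is a between-subjects factor, sampling period (on release vs
after 30 min habituation) a within-subjects factor.  Group-level
responses (mean polarization) get a random intercept per group;
individual-level responses (log median speed, log mean NND) additionally
get a random intercept per fish nested within group.

Models are fitted by REML.  t-statistics use *containment* degrees of
freedom, assigned per term at the level of the grouping hierarchy within
which the term varies:

    df_level = m_level - (m_parent + p_level)

where ``m_level`` is the number of units at that level, ``m_parent`` the
number at the enclosing level, and ``p_level`` the number of fixed-effect
columns estimated at that level.  For the standard design of 12 groups x
2 periods this gives df = 10 for the between-groups familiarity term and
df = 10 (group level) or df = 46 (48 fish x 2 periods) for within-subject
terms — the convention used by nlme's ``lme``.

Fixed-effect coding: ``familiarity`` = 1 for familiar groups (0 for
unfamiliar), ``time`` = 1 for the second sampling period, plus their
interaction; a positive familiarity estimate therefore means familiar
groups score higher in the first period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import ConfigError, DataError

MODEL_TERMS = ("intercept", "familiarity", "time", "fam_x_time")


@dataclass(frozen=True)
class ModelFit:
    """One fixed-effect row: estimate, s.e., CI, t, containment df, p."""

    response: str
    term: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    t_value: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg step-up outcome, aligned with the input order."""

    p_values: np.ndarray
    q_threshold: float
    significant: np.ndarray  # bool, input order
    n_significant: int
    adjusted: np.ndarray  # BH-adjusted p-values, input order


def _check_balance(df: pd.DataFrame, unit_cols: list[str]) -> None:
    counts = df.groupby(unit_cols + ["period"], observed=True).size()
    units = df[unit_cols].drop_duplicates()
    expected = len(units) * 2
    if len(counts) != expected or (counts != 1).any():
        present = set(counts.index)
        missing = []
        for _, u in units.iterrows():
            for per in ("period1", "period2"):
                key = tuple(u) + (per,)
                if key not in present:
                    missing.append(key)
        raise DataError(
            f"unbalanced repeated-measures table; missing or duplicated cells: "
            f"{missing if missing else sorted(present)}"
        )
    treatments = set(df["treatment"].unique())
    if treatments != {"familiar", "unfamiliar"}:
        raise DataError(f"both treatments required, got {sorted(treatments)}")


def _design(df: pd.DataFrame) -> np.ndarray:
    fam = (df["treatment"] == "familiar").to_numpy(dtype=float)
    per = (df["period"] == "period2").to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), fam, per, fam * per])


def _best_reml_fit(model):
    """REML fit, robust to variance components at the zero boundary.

    lbfgs can stall short of a boundary optimum; powell reaches it.  Fit
    with both and keep the higher restricted likelihood.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method, maxiter=2000)
            except Exception:
                continue
            if best is None or res.llf > best.llf:
                best = res
        if best is None:
            best = model.fit(reml=True)
    return best


def _fit_mixed(y, X, groups):
    return _best_reml_fit(sm.MixedLM(y, X, groups=groups))


def _rows(response, res, dfs) -> list[ModelFit]:
    rows = []
    for j, term in enumerate(MODEL_TERMS):
        est = float(np.asarray(res.fe_params)[j])
        se = float(np.asarray(res.bse_fe)[j])
        df = int(dfs[j])
        tval = est / se
        p = float(2.0 * sps.t.sf(abs(tval), df))
        tcrit = float(sps.t.ppf(0.975, df))
        rows.append(
            ModelFit(
                response=response,
                term=term,
                estimate=est,
                std_error=se,
                ci_low=est - tcrit * se,
                ci_high=est + tcrit * se,
                t_value=tval,
                df=df,
                p_value=p,
            )
        )
    return rows


def fit_group_model(records: pd.DataFrame, response_col: str = "mean_polarization") -> list[ModelFit]:
    """Split-plot model for the group-level response (mean polarization).

    ``records`` needs columns trial_id, treatment, period and the
    response; each trial must appear exactly once per period.
    """
    df = records.reset_index(drop=True)
    _check_balance(df, ["trial_id"])
    y = df[response_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError(f"non-finite values in {response_col}")
    X = _design(df)
    res = _fit_mixed(y, X, df["trial_id"].to_numpy())
    n_groups = df["trial_id"].nunique()
    n_obs = len(df)
    df_between = n_groups - 2  # m_group - (m_pop + familiarity)
    df_within = n_obs - n_groups - 2  # residual level: time + interaction
    dfs = [df_within, df_between, df_within, df_within]
    return _rows(response_col, res, dfs)


def fit_individual_model(records: pd.DataFrame, response: str) -> list[ModelFit]:
    """Split-plot model with fish nested in group, on a log response.

    ``response`` is ``"log_speed"`` (from column median_speed) or
    ``"log_nnd"`` (from mean_nnd); values are natural-log transformed and
    must be strictly positive.
    """
    col = {"log_speed": "median_speed", "log_nnd": "mean_nnd"}.get(response)
    if col is None:
        raise ConfigError(f"unknown response {response!r}; use log_speed or log_nnd")
    df = records.reset_index(drop=True)
    _check_balance(df, ["trial_id", "fish_id"])
    vals = df[col].to_numpy(dtype=float)
    bad = ~(np.isfinite(vals) & (vals > 0))
    if bad.any():
        offending = df.loc[bad, ["trial_id", "fish_id", "period"]].to_dict("records")
        raise DataError(f"nonpositive/missing {col} before log transform: {offending}")
    y = np.log(vals)
    X = _design(df)
    # random intercept per fish nested within group
    fish = df["trial_id"].astype(str) + "/" + df["fish_id"].astype(str)
    d = pd.DataFrame(
        {
            "y": y,
            "familiarity": X[:, 1],
            "time_": X[:, 2],
            "trial_id": df["trial_id"].to_numpy(),
            "fish_uid": fish.to_numpy(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "y ~ familiarity + time_ + familiarity:time_",
            groups="trial_id",
            re_formula="1",
            vc_formula={"fish": "0 + C(fish_uid)"},
            data=d,
        )
    res = _best_reml_fit(model)
    n_groups = df["trial_id"].nunique()
    n_fish = fish.nunique()
    n_obs = len(df)
    df_between = n_groups - 2
    df_within = n_obs - n_fish - 2
    dfs = [df_within, df_between, df_within, df_within]
    return _rows(response, res, dfs)


def fits_table(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])


# ---------------------------------------------------------------------------
# Assumption diagnostics
# ---------------------------------------------------------------------------

def assumption_checks(
    df: pd.DataFrame,
    value_col: str,
    cell_cols: tuple[str, ...] = ("treatment", "period"),
) -> dict:
    """Shapiro per design cell, median-centred Levene across cells, Q-Q data.

    Returns a dict with keys ``shapiro`` (DataFrame), ``levene``
    (statistic, p) and ``qq`` (theoretical vs ordered sample quantiles of
    the pooled, cell-centred values).  Constant cells are flagged, not
    fatal.
    """
    rows = []
    samples = []
    centred = []
    for key, sub in df.groupby(list(cell_cols), observed=True):
        vals = sub[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            raise DataError(f"cell {key}: need >= 3 values for diagnostics")
        degenerate = bool(np.ptp(vals) == 0)
        if degenerate:
            stat, p = np.nan, np.nan
        else:
            stat, p = sps.shapiro(vals)
        rows.append(
            dict(zip(cell_cols, key if isinstance(key, tuple) else (key,)))
            | {"n": len(vals), "shapiro_stat": stat, "shapiro_p": p, "degenerate": degenerate}
        )
        samples.append(vals)
        centred.append(vals - np.median(vals))
    if len(samples) < 2 or all(r["degenerate"] for r in rows):
        lev_stat, lev_p = np.nan, np.nan  # variance comparison needs >= 2 cells
    else:
        lev_stat, lev_p = sps.levene(*samples, center="median")
    pooled = np.sort(np.concatenate(centred))
    osm, osr = sps.probplot(pooled, dist="norm", fit=False)
    return {
        "shapiro": pd.DataFrame(rows),
        "levene": {"statistic": float(lev_stat), "p_value": float(lev_p)},
        "qq": pd.DataFrame({"theoretical": osm, "sample": osr}),
    }


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control.

    Sort the m p-values ascending, find the largest k with
    ``p_(k) <= k * q / m``, and call the k smallest significant.  The
    significance set is always a prefix of the sorted p-values, and
    lowering any p-value can only grow it.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p_values must be a non-empty 1-D collection")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(ranked <= thresh)
    k = int(passing[-1]) + 1 if passing.size else 0
    significant = np.zeros(m, dtype=bool)
    significant[order[:k]] = True
    # step-up adjusted p-values (monotone from the largest down)
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return FdrResult(
        p_values=p,
        q_threshold=q,
        significant=significant,
        n_significant=k,
        adjusted=adjusted,
    )
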