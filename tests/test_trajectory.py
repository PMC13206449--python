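"""Trajectory model: exact cases, group-mean oracle, statsmodels cross-check."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tivbench import (MeasureMatrix, SampleDesign, SimulationConfig, fit_trajectory,
                      simulate_cohort)
from tivbench.trajectory import zscore

SEED = 7


def _design(cohort):
    return SampleDesign(label="all", member_ids=list(cohort.index))


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimulationConfig(n_per_sex=150, seed=SEED))


def test_outcome_equal_to_zscored_age(cohort):
    z = zscore(cohort["age_months"].to_numpy())
    matrix = MeasureMatrix(values=pd.DataFrame({"u0": z}, index=cohort.index))
    est = fit_trajectory(matrix, cohort, _design(cohort))
    assert est.coef.loc["u0", "age"] == pytest.approx(1.0, abs=1e-10)
    assert est.coef.loc["u0", "sex"] == pytest.approx(0.0, abs=1e-10)
    assert est.coef.loc["u0", "age_sex"] == pytest.approx(0.0, abs=1e-10)
    assert est.adj_r2["u0"] == pytest.approx(1.0, abs=1e-10)


def test_sex_coefficient_equals_group_mean_oracle():
    """With age orthogonalized, the sex estimate is the standardized F-M gap."""
    rng = np.random.default_rng(SEED)
    n = 200
    sex = np.repeat(["F", "M"], n // 2)
    age = np.tile(np.arange(n // 2), 2) + 600  # identical per group -> orthogonal
    y = rng.normal(0, 1, n) + 0.8 * (sex == "M")
    cohort = pd.DataFrame({"sex": sex, "age_months": age, "tiv": 1.4e6},
                          index=[f"p{i}" for i in range(n)])
    matrix = MeasureMatrix(values=pd.DataFrame({"u0": y}, index=cohort.index))
    est = fit_trajectory(matrix, cohort, _design(cohort))
    z = (y - y.mean()) / y.std(ddof=1)
    oracle = z[sex == "M"].mean() - z[sex == "F"].mean()
    assert est.coef.loc["u0", "sex"] == pytest.approx(oracle, rel=1e-10)


def test_covariate_recovers_tiv_coefficient_and_shrinks_sex(cohort):
    rng = np.random.default_rng(SEED)
    z_tiv = zscore(cohort["tiv"].to_numpy())
    y = 0.5 * z_tiv + rng.normal(0, 0.5, len(cohort))
    matrix = MeasureMatrix(values=pd.DataFrame({"u0": y}, index=cohort.index))
    eq1 = fit_trajectory(matrix, cohort, _design(cohort))
    eq5 = fit_trajectory(matrix, cohort, _design(cohort), include_covariate=True)
    assert eq5.model == "eq5" and "global" in eq5.coef.columns
    # outcome is z-scored, so the standardized TIV coefficient is 0.5/sd(y)
    expected = 0.5 / y.std(ddof=1)
    assert eq5.coef.loc["u0", "global"] == pytest.approx(expected, abs=0.08)
    assert abs(eq5.coef.loc["u0", "sex"]) < abs(eq1.coef.loc["u0", "sex"])


def test_matches_statsmodels_ols_exactly(cohort):
    """Dual route: batched linear algebra vs statsmodels, eq1 and eq5."""
    rng = np.random.default_rng(SEED)
    Y = pd.DataFrame(rng.normal(size=(len(cohort), 4)),
                     index=cohort.index, columns=[f"u{j}" for j in range(4)])
    matrix = MeasureMatrix(values=Y)
    for include in (False, True):
        est = fit_trajectory(matrix, cohort, _design(cohort), include_covariate=include)
        z_age = zscore(cohort["age_months"].to_numpy())
        sex = (cohort["sex"] == "M").to_numpy(float)
        cols = {"intercept": np.ones(len(cohort)), "age": z_age, "sex": sex,
                "age_sex": z_age * sex}
        if include:
            cols["global"] = zscore(cohort["tiv"].to_numpy())
        X = pd.DataFrame(cols)
        for u in Y.columns:
            z = zscore(Y[u].to_numpy())
            fit = sm.OLS(z, X.to_numpy()).fit()
            np.testing.assert_allclose(est.coef.loc[u], fit.params, rtol=1e-9)
            np.testing.assert_allclose(est.se.loc[u], fit.bse, rtol=1e-9)
            np.testing.assert_allclose(est.pvalues.loc[u], fit.pvalues, rtol=1e-8, atol=1e-12)
            assert est.adj_r2[u] == pytest.approx(fit.rsquared_adj, rel=1e-9)


def test_frisch_waugh_equivalence_of_covariate_and_residuals():
    """With g orthogonal to all model terms, eq5 estimates equal eq1 on the
    residuals-adjusted outcome (slope fitted on the same sample)."""
    rng = np.random.default_rng(SEED)
    n = 400
    sex = np.repeat(["F", "M"], n // 2)
    age = rng.integers(600, 900, n)
    z_age = zscore(age.astype(float))
    sexi = (sex == "M").astype(float)
    X = np.column_stack([np.ones(n), z_age, sexi, z_age * sexi])
    g_raw = rng.normal(1.4e6, 1e5, n)
    # orthogonalize g against the design so Frisch-Waugh applies exactly
    g = g_raw - X @ np.linalg.lstsq(X, g_raw, rcond=None)[0] + 1.4e6
    y = 2e-3 * (g - 1.4e6) + rng.normal(0, 1, n) + 0.5 * sexi
    cohort = pd.DataFrame({"sex": sex, "age_months": age, "tiv": g},
                          index=[f"p{i}" for i in range(n)])
    matrix = MeasureMatrix(values=pd.DataFrame({"u0": y}, index=cohort.index))
    design = _design(cohort)

    from tivbench import apply_adjustment
    adj, _ = apply_adjustment(matrix, cohort, "residuals")
    eq1_resid = fit_trajectory(adj, cohort, design)
    eq5 = fit_trajectory(matrix, cohort, design, include_covariate=True)
    for term in ("age", "sex", "age_sex"):
        # identical up to the outcome rescaling: compare correlation-free ratio
        a = eq1_resid.coef.loc["u0", term]
        b = eq5.coef.loc["u0", term]
        scale = eq1_resid.coef.loc["u0", "age"] / eq5.coef.loc["u0", "age"] \
            if term != "age" else a / b
        assert a == pytest.approx(b * scale, rel=1e-6)


def test_zero_variance_unit_skipped(cohort):
    vals = pd.DataFrame({"flat": 3.0, "ok": np.arange(len(cohort), dtype=float)},
                        index=cohort.index)
    est = fit_trajectory(MeasureMatrix(values=vals), cohort, _design(cohort))
    assert "flat" in est.skipped_units
    assert list(est.unit_ids) == ["ok"]


def test_too_small_sample_errors(cohort):
    ids = list(cohort.index[:4])
    design = SampleDesign(label="tiny", member_ids=ids)
    vals = pd.DataFrame({"u0": [1.0, 2.0, 3.0, 4.0]}, index=ids)
    with pytest.raises(ValueError, match="too small"):
        fit_trajectory(MeasureMatrix(values=vals), cohort, design)


def test_missing_rows_detected(cohort):
    design = SampleDesign(label="bad", member_ids=list(cohort.index) + ["ghost"])
    vals = pd.DataFrame({"u0": np.arange(len(cohort), dtype=float)}, index=cohort.index)
    with pytest.raises(ValueError, match="absent"):
        fit_trajectory(MeasureMatrix(values=vals), cohort, design)


def test_nan_units_fit_on_observed_rows(cohort):
    rng = np.random.default_rng(SEED)
    y = rng.normal(size=len(cohort))
    y_nan = y.copy()
    y_nan[:10] = np.nan
    vals = pd.DataFrame({"u0": y_nan}, index=cohort.index)
    est = fit_trajectory(MeasureMatrix(values=vals), cohort, _design(cohort))
    # oracle: statsmodels on the observed rows; predictors z-scored on the
    # full design sample (z-scoring is a sample-level convention), only the
    # unit's missing rows are dropped
    keep = ~np.isnan(y_nan)
    z_age = zscore(cohort["age_months"].to_numpy())[keep]
    sexi = (cohort["sex"] == "M").to_numpy(float)[keep]
    X = np.column_stack([np.ones(keep.sum()), z_age, sexi, z_age * sexi])
    fit = sm.OLS(zscore(y_nan[keep]), X).fit()
    np.testing.assert_allclose(est.coef.loc["u0"], fit.params, rtol=1e-9)
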