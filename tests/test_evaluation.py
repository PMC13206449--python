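"""Comparison statistics vs closed-form oracles; BH-FDR; partial-R^2 control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tivbench import (MeasureMatrix, SampleDesign, SimulationConfig, apply_adjustment,
                      benjamini_hochberg, compare_estimates, fit_summary,
                      fit_trajectory, partial_r2_control, simulate_cohort,
                      simulate_measures)
from tivbench.trajectory import TrajectoryEstimates

SEED = 7


def _estimates(coef: pd.DataFrame, sample="s", method="m") -> TrajectoryEstimates:
    like = coef * 0.0
    return TrajectoryEstimates(coef=coef, se=like, pvalues=like + 1.0,
                               adj_r2=pd.Series(0.3, index=coef.index),
                               n=100, model="eq1", sample=sample, method=method)


def _frame(values, terms=("age", "sex", "age_sex")):
    arr = np.asarray(values, dtype=float)
    units = pd.Index([f"u{i}" for i in range(arr.shape[0])], name="unit")
    return pd.DataFrame(arr, index=units, columns=list(terms))


def test_identical_vectors_give_identity_statistics():
    rng = np.random.default_rng(SEED)
    ref = _estimates(_frame(rng.normal(size=(12, 3))))
    rep = compare_estimates(ref, ref)
    for term in ("age", "sex", "age_sex"):
        row = rep.table.loc[term]
        assert row["r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["t"] == 0.0 and row["p_raw"] == 1.0 and row["cohens_d"] == 0.0


def test_halved_vector_gives_slope_half():
    rng = np.random.default_rng(SEED)
    coef = _frame(rng.normal(size=(15, 3)))
    rep = compare_estimates(_estimates(coef), _estimates(coef * 0.5))
    for term in ("age", "sex", "age_sex"):
        assert rep.table.loc[term, "r"] == pytest.approx(1.0)
        assert rep.table.loc[term, "slope"] == pytest.approx(0.5)


def test_comparison_matches_closed_form_oracle():
    """r, slope, paired t, paired d against direct formulas, 1e-10 relative."""
    rng = np.random.default_rng(SEED)
    for _ in range(50):
        x = rng.normal(size=10)
        y = 0.7 * x + rng.normal(scale=0.4, size=10)
        ref = _estimates(_frame(np.column_stack([x, x, x])))
        test = _estimates(_frame(np.column_stack([y, y, y])))
        row = compare_estimates(ref, test).table.loc["sex"]
        xc, yc = x - x.mean(), y - y.mean()
        r_o = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        slope_o = (xc @ yc) / (xc @ xc)
        d = y - x
        sd = d.std(ddof=1)
        t_o = d.mean() / (sd / np.sqrt(len(d)))
        d_o = d.mean() / sd
        assert row["r"] == pytest.approx(r_o, rel=1e-10)
        assert row["slope"] == pytest.approx(slope_o, rel=1e-10)
        assert row["t"] == pytest.approx(t_o, rel=1e-10)
        assert row["cohens_d"] == pytest.approx(d_o, rel=1e-10)


def test_slope_direction_flag():
    rng = np.random.default_rng(SEED)
    coef = _frame(rng.normal(size=(15, 3)))
    ref, test = _estimates(coef), _estimates(coef * 0.5)
    fwd = compare_estimates(ref, test).table.loc["sex", "slope"]
    rev = compare_estimates(ref, test, slope_direction="ref_on_test").table.loc["sex", "slope"]
    assert fwd == pytest.approx(0.5) and rev == pytest.approx(2.0)


def test_mismatched_units_error():
    rng = np.random.default_rng(SEED)
    ref = _estimates(_frame(rng.normal(size=(8, 3))))
    other = _frame(rng.normal(size=(8, 3)))
    other.index = [f"v{i}" for i in range(8)]
    with pytest.raises(ValueError, match="symmetric difference"):
        compare_estimates(ref, _estimates(other))


def test_zero_variance_reference_error():
    const = _frame(np.ones((6, 3)))
    varying = _frame(np.random.default_rng(SEED).normal(size=(6, 3)))
    with pytest.raises(ValueError, match="zero variance"):
        compare_estimates(_estimates(const), _estimates(varying))


def test_bh_hand_computed_example():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_edge_cases():
    np.testing.assert_allclose(benjamini_hochberg([0.42]), [0.42])
    np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
def test_bh_against_step_up_oracle(ps):
    """Independent step-up implementation of the BH procedure."""
    p = np.array(ps)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end  # 1-based rank
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    got = benjamini_hochberg(p)
    np.testing.assert_allclose(got, adj, rtol=1e-12, atol=1e-15)
    assert (got >= p - 1e-15).all() and (got <= 1.0).all()


def test_fit_summary_arithmetic_and_oracle():
    units = pd.Index(["u0", "u1"], name="unit")
    est = TrajectoryEstimates(
        coef=pd.DataFrame(0.0, index=units, columns=["age"]),
        se=pd.DataFrame(0.0, index=units, columns=["age"]),
        pvalues=pd.DataFrame(1.0, index=units, columns=["age"]),
        adj_r2=pd.Series([0.1, 0.5], index=units),
        n=50, model="eq1", sample="s", method="m")
    row = fit_summary(est).iloc[0]
    assert row["mean"] == pytest.approx(0.3)
    assert row["min"] == pytest.approx(0.1) and row["max"] == pytest.approx(0.5)
    assert row["sd"] == pytest.approx(np.std([0.1, 0.5], ddof=1))
    with pytest.raises(ValueError):
        fit_summary([])


@pytest.fixture(scope="module")
def ct_like():
    """Thickness-like data: nearly head-size independent before adjustment."""
    cfg = SimulationConfig(n_per_sex=500, seed=SEED, n_units=10,
                           metric="cortical_thickness", ct_beta=0.02,
                           alpha_range=(0.5, 0.6), noise_cv=0.05,
                           age_slope_range=(-0.01, -0.005))
    cohort = simulate_cohort(cfg)
    matrix, truth = simulate_measures(cohort, cfg)
    design = SampleDesign(label="all", member_ids=list(cohort.index))
    return cohort, matrix, design


def test_partial_r2_identity_when_outcome_orthogonal_to_g(ct_like):
    cohort, matrix, design = ct_like
    raw = fit_trajectory(matrix, cohort, design)
    part = partial_r2_control(matrix, cohort, design)
    # ct_beta ~ 0: partialling TIV barely changes the fit
    np.testing.assert_allclose(part, raw.adj_r2.loc[part.index], atol=0.02)


def test_partial_r2_collapses_for_pure_g_outcome(ct_like):
    cohort, _, design = ct_like
    rng = np.random.default_rng(SEED)
    # linear in g up to tiny independent noise: partialling removes the signal
    vals = pd.DataFrame({"u0": 3e-6 * cohort["tiv"] + rng.normal(0, 1e-3, len(cohort))},
                        index=cohort.index)
    raw = fit_trajectory(MeasureMatrix(values=vals), cohort, design).adj_r2["u0"]
    part = partial_r2_control(MeasureMatrix(values=vals), cohort, design)["u0"]
    assert raw > 0.3          # g-driven sex difference dominates the raw fit
    assert abs(part) < 0.02   # nothing left once g is partialled out


def test_proportions_on_thickness_injects_tiv_signal(ct_like):
    """The partial-correlation control detects proportion-injected TIV R^2."""
    cohort, matrix, design = ct_like
    adj, _ = apply_adjustment(matrix, cohort, "proportions")
    plain = fit_trajectory(adj, cohort, design).adj_r2
    partialled = partial_r2_control(adj, cohort, design)
    assert partialled.mean() < plain.mean() - 0.1
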