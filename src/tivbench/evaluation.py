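"""Comparison of estimate vectors across samples and correction methods.

The gold standard is the raw-value fit on the matched sample; a correction is
judged by how well the per-unit standardized estimates it yields in another
sample reproduce the gold-standard vector:

* Pearson r — strength of the linear association;
* OLS slope of test on reference — systematic over/under-estimation
  (ideal slope 1);
* paired t-test and paired Cohen's d over per-unit differences, with
  Benjamini-Hochberg FDR across the report's terms;
* adjusted-R^2 summaries per method, and a partial-correlation control that
  detects head-size signal injected by an adjustment (e.g. dividing a nearly
  head-size-independent measure by TIV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sampling import SampleDesign
from .simulate import MeasureMatrix
from .trajectory import TrajectoryEstimates, fit_trajectory

__all__ = [
    "ComparisonReport",
    "compare_estimates",
    "benjamini_hochberg",
    "fit_summary",
    "partial_r2_control",
]


@dataclass
class ComparisonReport:
    """Per-term comparison statistics; ``table`` is indexed by term."""

    table: pd.DataFrame
    ref_label: str = ""
    test_label: str = ""

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH-adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _paired_stats(diff: np.ndarray) -> tuple[float, float, float]:
    """Paired t, raw p and Cohen's d; zero differences give (0, 1, 0)."""
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0, 0.0
    n = len(diff)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    d = diff.mean() / sd
    return float(t), float(p), float(d)


def compare_estimates(
    ref: TrajectoryEstimates,
    test: TrajectoryEstimates,
    terms: Sequence[str] = ("age", "sex", "age_sex"),
    slope_direction: str = "test_on_ref",
) -> ComparisonReport:
    """Compare per-unit estimate vectors of ``test`` against ``ref``.

    Units must coincide (order is reconciled by unit id); at least 3 shared
    units are required. ``slope_direction='ref_on_test'`` flips the
    regression direction.
    """
    if slope_direction not in ("test_on_ref", "ref_on_test"):
        raise ValueError(f"unknown slope_direction {slope_direction!r}")
    ref_units = set(ref.unit_ids)
    test_units = set(test.unit_ids)
    if ref_units != test_units:
        diff = sorted(ref_units ^ test_units)
        raise ValueError(f"unit sets differ; symmetric difference (first 10): {diff[:10]}")
    units = ref.unit_ids
    if len(units) < 3:
        raise ValueError("need at least 3 units to compare estimate vectors")

    rows = []
    raw_ps = []
    for term in terms:
        if term not in ref.coef.columns or term not in test.coef.columns:
            raise ValueError(f"term {term!r} absent from one of the estimate tables")
        x = ref.coef[term].to_numpy(dtype=float)
        y = test.coef.loc[units, term].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            raise ValueError(f"zero variance in reference estimates for term {term!r}: slope undefined")
        r = float(stats.pearsonr(x, y)[0])
        a, b = (x, y) if slope_direction == "test_on_ref" else (y, x)
        slope = float(np.polyfit(a, b, 1)[0])
        t, p_raw, d = _paired_stats(y - x)
        raw_ps.append(p_raw)
        rows.append({"term": term, "r": r, "slope": slope, "t": t, "p_raw": p_raw,
                     "cohens_d": d, "n_units": len(units)})

    table = pd.DataFrame(rows).set_index("term")
    table["p_fdr"] = benjamini_hochberg(np.array(raw_ps))
    return ComparisonReport(
        table=table,
        ref_label=f"{ref.sample}/{ref.method}",
        test_label=f"{test.sample}/{test.method}",
    )


def fit_summary(
    estimates: Union[TrajectoryEstimates, Iterable[TrajectoryEstimates]],
) -> pd.DataFrame:
    """Mean / sd / range of adjusted R^2, keyed by (sample, method, model)."""
    if isinstance(estimates, TrajectoryEstimates):
        estimates = [estimates]
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates supplied")
    rows = []
    for est in estimates:
        r2 = est.adj_r2.to_numpy(dtype=float)
        if len(r2) == 0:
            raise ValueError("estimate table has no units")
        rows.append({
            "sample": est.sample, "method": est.method, "model": est.model,
            "mean": float(r2.mean()),
            "sd": float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
            "min": float(r2.min()), "max": float(r2.max()),
            "n_units": len(r2),
        })
    return pd.DataFrame(rows).set_index(["sample", "method", "model"])


def partial_r2_control(
    adjusted: MeasureMatrix,
    cohort: pd.DataFrame,
    design: SampleDesign,
    global_var: str = "tiv",
) -> pd.Series:
    """Adjusted R^2 after partialling the global variable out of the outcome.

    Residualizes each (already adjusted) unit on ``g`` within the design
    sample, re-z-scores the residuals and refits the base trajectory model.
    If an adjustment injected head-size signal (the proportions method on a
    nearly head-size-independent measure), the partialled R^2 collapses
    relative to the unpartialled one.
    """
    ids = pd.Index(design.member_ids)
    V = adjusted.values.loc[ids]
    g = cohort.loc[ids, global_var].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(ids)), g])

    Y = V.to_numpy(dtype=float)
    out = np.full_like(Y, np.nan)
    finite = ~np.isnan(Y)
    complete = finite.all(axis=0)
    if complete.any():
        coef, *_ = np.linalg.lstsq(X, Y[:, complete], rcond=None)
        out[:, complete] = Y[:, complete] - X @ coef
    for j in np.flatnonzero(~complete):
        keep = finite[:, j]
        if keep.sum() < 3:
            continue
        coef, *_ = np.linalg.lstsq(X[keep], Y[keep, j], rcond=None)
        out[keep, j] = Y[keep, j] - X[keep] @ coef

    resid = adjusted.copy_with(pd.DataFrame(out, index=ids, columns=V.columns))
    est = fit_trajectory(resid, cohort, design, include_covariate=False,
                         method_label=f"partial_{global_var}")
    return est.adj_r2
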