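"""Standardized aging-trajectory models.

Per measurement unit, an ordinary least-squares fit of

    z(outcome) ~ 1 + z(age) + sex + z(age):sex [+ z(g)]

within one subsample. Continuous predictors and the outcome are z-scored
within the analysis sample (the outcome *after* any value-transform
correction); sex enters as an unscaled 0/1 indicator with female as the
reference level, so the sex coefficient is a standardized mean difference,
and the interaction is the product of z-scored age with the indicator (not
re-scored). The optional global covariate term realizes the covariate
correction method.

Fits are batched across units (one shared design matrix, multi-column solve)
so vertexwise matrices are cheap; units with missing entries fall back to a
per-unit masked fit, and zero-variance units are skipped and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import SampleDesign
from .simulate import MeasureMatrix

__all__ = ["TrajectoryEstimates", "fit_trajectory", "zscore"]

TERMS_EQ1 = ("intercept", "age", "sex", "age_sex")
TERMS_EQ5 = TERMS_EQ1 + ("global",)


def zscore(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with sample sd (ddof=1), the convention of R scale()."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class TrajectoryEstimates:
    """Per-unit standardized coefficients of one (sample, method) fit.

    ``coef``, ``se`` and ``pvalues`` are units x terms frames; ``adj_r2`` is
    a per-unit Series. ``model`` is ``eq1`` (no global covariate) or ``eq5``.
    """

    coef: pd.DataFrame
    se: pd.DataFrame
    pvalues: pd.DataFrame
    adj_r2: pd.Series
    n: int
    model: str
    sample: str = ""
    method: str = ""
    skipped_units: list = field(default_factory=list)

    @property
    def terms(self) -> tuple:
        return tuple(self.coef.columns)

    @property
    def unit_ids(self) -> pd.Index:
        return self.coef.index

    def tidy(self) -> pd.DataFrame:
        """Long-format table: unit, term, estimate, se, p, adj_r2, ..."""
        rows = self.coef.stack().rename("estimate").reset_index()
        rows.columns = ["unit", "term", "estimate"]
        rows["se"] = self.se.stack().to_numpy()
        rows["p"] = self.pvalues.stack().to_numpy()
        rows["adj_r2"] = self.adj_r2.reindex(rows["unit"]).to_numpy()
        rows["n"] = self.n
        rows["model"] = self.model
        rows["sample"] = self.sample
        rows["method"] = self.method
        return rows


def _ols_stats(X: np.ndarray, Y: np.ndarray):
    """Batched OLS of each column of Y on X. Returns coef, se, p, adj_r2."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} observations but {p} parameters: model not identifiable")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    rss = (resid**2).sum(axis=0)
    dof = n - p
    sigma2 = rss / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ym = Y.mean(axis=0)
    tss = ((Y - ym) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - rss / tss
    # p counts the intercept column, so n - p is the residual dof
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return coef, se, pvals, adj


def fit_trajectory(
    matrix: MeasureMatrix,
    cohort: pd.DataFrame,
    design: SampleDesign,
    include_covariate: bool = False,
    global_var: str = "tiv",
    method_label: str = "none",
) -> TrajectoryEstimates:
    """Fit the standardized trajectory model for every unit of ``matrix``.

    Parameters
    ----------
    include_covariate
        Add a z-scored global covariate term (the covariate method; model
        tag ``eq5``), otherwise the base model (``eq1``).
    method_label
        Stored on the result for bookkeeping (e.g. the correction applied
        upstream to the matrix values).

    Notes
    -----
    z-scores are recomputed within the design sample: each subsample is an
    independent analysis. Units whose outcome has zero variance (or too few
    non-missing rows) are skipped, not imputed, and listed in
    ``skipped_units``.
    """
    ids = pd.Index(design.member_ids)
    missing = ids.difference(matrix.values.index)
    if len(missing):
        raise ValueError(f"design members absent from matrix: {list(missing[:5])}")
    missing = ids.difference(cohort.index)
    if len(missing):
        raise ValueError(f"design members absent from cohort: {list(missing[:5])}")

    sub = cohort.loc[ids]
    V = matrix.values.loc[ids]
    n = len(ids)

    z_age = zscore(sub["age_months"].to_numpy(dtype=float))
    sex = (sub["sex"] == "M").to_numpy(dtype=float)
    cols = [np.ones(n), z_age, sex, z_age * sex]
    terms = list(TERMS_EQ1)
    if include_covariate:
        if global_var not in cohort.columns:
            raise ValueError(f"global variable {global_var!r} not in cohort")
        cols.append(zscore(sub[global_var].to_numpy(dtype=float)))
        terms.append("global")
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"sample size {n} too small for {p} model terms")

    Y = V.to_numpy(dtype=float)
    units = V.columns
    nan_any = np.isnan(Y).any(axis=0)
    sd = np.nanstd(Y, axis=0, ddof=1)
    n_obs = (~np.isnan(Y)).sum(axis=0)
    usable = (sd > 0) & (n_obs > p + 1)
    skipped = list(units[~usable])

    coef = np.full((len(units), p), np.nan)
    se = np.full_like(coef, np.nan)
    pv = np.full_like(coef, np.nan)
    adj = np.full(len(units), np.nan)

    # Fast path: fully observed units share one solve.
    full = usable & ~nan_any
    if full.any():
        Yf = Y[:, full]
        mu = Yf.mean(axis=0)
        s = Yf.std(axis=0, ddof=1)
        Z = (Yf - mu) / s
        c, e, q, a = _ols_stats(X, Z)
        coef[full] = c.T
        se[full] = e.T
        pv[full] = q.T
        adj[full] = a

    for j in np.flatnonzero(usable & nan_any):
        keep = ~np.isnan(Y[:, j])
        y = Y[keep, j]
        s = y.std(ddof=1)
        if s == 0 or keep.sum() <= p + 1:
            skipped.append(units[j])
            continue
        z = ((y - y.mean()) / s)[:, None]
        c, e, q, a = _ols_stats(X[keep], z)
        coef[j] = c[:, 0]
        se[j] = e[:, 0]
        pv[j] = q[:, 0]
        adj[j] = a[0]

    keep_units = [u for u in units if u not in set(skipped)]
    idx = units.get_indexer(keep_units)
    return TrajectoryEstimates(
        coef=pd.DataFrame(coef[idx], index=pd.Index(keep_units, name="unit"), columns=terms),
        se=pd.DataFrame(se[idx], index=pd.Index(keep_units, name="unit"), columns=terms),
        pvalues=pd.DataFrame(pv[idx], index=pd.Index(keep_units, name="unit"), columns=terms),
        adj_r2=pd.Series(adj[idx], index=pd.Index(keep_units, name="unit"), name="adj_r2"),
        n=n,
        model="eq5" if include_covariate else "eq1",
        sample=design.label,
        method=method_label,
        skipped_units=skipped,
    )
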