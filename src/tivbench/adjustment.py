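"""Head-size correction methods.

Four corrections are benchmarked, any global measure (TIV, TCV, TSA, MCT, an
alternative TIV source) serving as adjusting variable ``g``:

* ``proportions`` — value / g; assumes strict proportionality (beta = 1).
* ``pcp`` — power-corrected proportions, value / g**b with b the OLS slope of
  log(value) on log(g); exact for power-law scaling.
* ``residuals`` — value - b * (g - mean(g)) with b the OLS slope of value on
  g; exact for linear scaling.
* ``covariate`` — g entered as a regressor in the trajectory model; realized
  in :mod:`tivbench.trajectory`, not as a value transform.

Slopes/exponents and the centering mean are estimated per measurement unit on
a *pooled* (both-sex) fitting sample: normalizing each group separately is
known to bias group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import MeasureMatrix

__all__ = [
    "AdjustmentSpec",
    "ADJUSTMENT_METHODS",
    "fit_power_exponent",
    "apply_adjustment",
]

ADJUSTMENT_METHODS = ("none", "proportions", "pcp", "residuals", "covariate")


@dataclass
class AdjustmentSpec:
    """Fitted parameters of one applied adjustment."""

    method: str
    global_var: str
    b: Optional[pd.Series] = None          # per-unit exponent (pcp) / slope (residuals)
    global_mean: Optional[float] = None    # mean of g over fitting sample (residuals)
    fitting_sample: Optional[list[str]] = None

    def __post_init__(self) -> None:
        needs_b = self.method in ("pcp", "residuals")
        if needs_b != (self.b is not None):
            raise ValueError(f"b must be present iff method is pcp/residuals (method={self.method})")
        if (self.method == "residuals") != (self.global_mean is not None):
            raise ValueError("global_mean must be present iff method is residuals")


def fit_power_exponent(moi, g, return_se: bool = False):
    """OLS slope of log(moi) on log(g), intercept included.

    This is the allometric exponent estimate ``b`` of the power-corrected
    proportions method. Raises if any value is non-positive (log undefined).
    """
    moi = np.asarray(moi, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(moi) | np.isnan(g))
    moi, g = moi[keep], g[keep]
    if (moi <= 0).any():
        bad = np.flatnonzero(moi <= 0)[:5]
        raise ValueError(f"non-positive measure values at positions {bad.tolist()}: log undefined")
    if (g <= 0).any():
        bad = np.flatnonzero(g <= 0)[:5]
        raise ValueError(f"non-positive global values at positions {bad.tolist()}: log undefined")
    if len(moi) < 3:
        raise ValueError("need at least 3 observations to fit an exponent")

    X = np.column_stack([np.ones(len(g)), np.log(g)])
    y = np.log(moi)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    b = float(coef[1])
    if not return_se:
        return b
    resid = y - X @ coef
    dof = len(y) - 2
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return b, se


def _nan_slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-column OLS slope of Y on x (intercept included), NaN-aware."""
    mask = ~np.isnan(Y)
    xx = np.where(mask, x[:, None], np.nan)
    n = mask.sum(axis=0).astype(float)
    xm = np.nansum(xx, axis=0) / n
    ym = np.nansum(np.where(mask, Y, 0.0), axis=0) / n
    xc = np.where(mask, x[:, None] - xm, 0.0)
    yc = np.where(mask, Y - ym, 0.0)
    sxx = (xc**2).sum(axis=0)
    sxy = (xc * yc).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sxx > 0, sxy / sxx, 0.0)


def apply_adjustment(
    matrix: MeasureMatrix,
    cohort: pd.DataFrame,
    method: str,
    global_var: str = "tiv",
    fitting_sample: Optional[Sequence[str]] = None,
    b_override: Optional[pd.Series] = None,
) -> tuple[MeasureMatrix, AdjustmentSpec]:
    """Apply a value-transform correction to every unit of ``matrix``.

    Parameters
    ----------
    fitting_sample
        Participant ids used to estimate per-unit slopes/exponents and the
        centering mean; defaults to all rows of the matrix (pooled sexes).
    b_override
        Per-unit exponents/slopes to use instead of fitting (e.g. forcing
        the PCP exponent to 1, which reduces it to proportions).

    Returns
    -------
    (MeasureMatrix, AdjustmentSpec)

    Notes
    -----
    Missing entries propagate as missing. ``method='covariate'`` is rejected
    here: it is a model term, not a value transform.
    """
    if method == "covariate":
        raise ValueError("the covariate method is realized in the trajectory model, not as a transform")
    if method not in ("none", "proportions", "pcp", "residuals"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if global_var not in cohort.columns:
        raise ValueError(f"global variable {global_var!r} not in cohort")

    V = matrix.values
    ids = V.index
    missing_rows = ids.difference(cohort.index)
    if len(missing_rows):
        raise ValueError(f"{len(missing_rows)} matrix rows absent from cohort (e.g. {missing_rows[0]!r})")
    g = cohort.loc[ids, global_var].to_numpy(dtype=float)

    if fitting_sample is None:
        fit_ids = list(ids)
    else:
        fit_ids = list(fitting_sample)
        extra = set(fit_ids) - set(ids)
        if extra:
            raise ValueError(f"fitting_sample ids not in matrix rows: {sorted(extra)[:5]}")

    if method == "none":
        return matrix.copy_with(V.copy()), AdjustmentSpec(method="none", global_var=global_var)

    if method in ("proportions", "pcp") and (g <= 0).any():
        raise ValueError(f"{method} requires strictly positive {global_var!r}")

    fit_pos = ids.get_indexer(fit_ids)
    arr = V.to_numpy(dtype=float)

    if method == "proportions":
        out = arr / g[:, None]
        spec = AdjustmentSpec(method=method, global_var=global_var)

    elif method == "pcp":
        if b_override is not None:
            b = b_override.reindex(V.columns).to_numpy(dtype=float)
        else:
            sub = arr[fit_pos]
            if np.nanmin(sub) <= 0:
                bad = V.columns[(np.nan_to_num(sub, nan=1.0) <= 0).any(axis=0)]
                raise ValueError(f"non-positive values in units {list(bad[:5])}: log undefined for pcp")
            b = _nan_slopes(np.log(g[fit_pos]), np.log(sub))
        out = arr / g[:, None] ** b[None, :]
        spec = AdjustmentSpec(
            method=method, global_var=global_var,
            b=pd.Series(b, index=V.columns, name="b"), fitting_sample=fit_ids,
        )

    else:  # residuals
        if b_override is not None:
            b = b_override.reindex(V.columns).to_numpy(dtype=float)
        else:
            b = _nan_slopes(g[fit_pos], arr[fit_pos])
        gbar = float(np.mean(g[fit_pos]))
        out = arr - b[None, :] * (g - gbar)[:, None]
        spec = AdjustmentSpec(
            method=method, global_var=global_var,
            b=pd.Series(b, index=V.columns, name="b"), global_mean=gbar, fitting_sample=fit_ids,
        )

    frame = pd.DataFrame(out, index=ids, columns=V.columns)
    return matrix.copy_with(frame), spec
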