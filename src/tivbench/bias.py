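"""Residual-bias maps and the spatial spin permutation test.

After correction, an ideal method reproduces the gold-standard estimate in
every unit. The remaining bias is the signed orthogonal distance of the point
(reference, test) from the identity line: ``(test - ref) / sqrt(2)``, positive
when the corrected estimate still leans toward the male direction
(undercorrection).

Whether a bias map aligns with the allometry (exponent) map is assessed with
a spin test: unit centroids live on the unit sphere, a uniform random 3D
rotation is applied (mirrored on the contralateral hemisphere), each unit
takes the value of its nearest rotated neighbor, and the map correlation is
recomputed; the empirical p-value is the proportion of null correlations
exceeding the observed one, with a +1 correction so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import TrajectoryEstimates

__all__ = [
    "BiasMap",
    "SpinResult",
    "bias_map",
    "fibonacci_coordinates",
    "spin_test",
]


@dataclass
class BiasMap:
    """Per-unit signed orthogonal-distance bias for one model term."""

    values: pd.Series
    term: str
    method: str = ""

    @property
    def unit_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class SpinResult:
    """Observed map correlation and its rotation-based null."""

    r_observed: float
    n_perm: int
    p_value: float
    null_r: np.ndarray
    alternative: str = "greater"

    def null_summary(self) -> dict:
        return {
            "mean": float(self.null_r.mean()),
            "sd": float(self.null_r.std(ddof=1)),
            "q95": float(np.quantile(self.null_r, 0.95)),
        }


def bias_map(ref: TrajectoryEstimates, test: TrajectoryEstimates, term: str = "sex",
             method: Optional[str] = None) -> BiasMap:
    """Signed orthogonal distance of (ref, test) estimate pairs from y = x."""
    if set(ref.unit_ids) != set(test.unit_ids):
        diff = sorted(set(ref.unit_ids) ^ set(test.unit_ids))
        raise ValueError(f"unit sets differ; symmetric difference (first 10): {diff[:10]}")
    units = ref.unit_ids
    r = ref.coef[term]
    t = test.coef.loc[units, term]
    vals = (t - r) / np.sqrt(2.0)
    return BiasMap(values=vals.rename("bias"), term=term,
                   method=method if method is not None else test.method)


def fibonacci_coordinates(n_units: int, unit_ids=None) -> pd.DataFrame:
    """Quasi-uniform unit centroids on the unit sphere (Fibonacci lattice).

    Hemisphere is assigned by the sign of x ('L' for x < 0). Stands in for a
    real parcellation's spherical centroids, which the package does not ship.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    i = np.arange(n_units, dtype=float)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_units
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    x, y = r * np.cos(theta), r * np.sin(theta)
    if unit_ids is None:
        unit_ids = [f"u{j:04d}" for j in range(n_units)]
    coords = pd.DataFrame(
        {"x": x, "y": y, "z": z, "hemisphere": np.where(x < 0, "L", "R")},
        index=pd.Index(unit_ids, name="unit"),
    )
    return coords


_MIRROR = np.diag([-1.0, 1.0, 1.0])  # flip x: left-right mirror


def _as_series(m, coords: pd.DataFrame) -> pd.Series:
    if isinstance(m, BiasMap):
        m = m.values
    s = pd.Series(m)
    missing = coords.index.difference(s.index)
    if len(missing):
        raise ValueError(f"map has no value for units {list(missing[:5])}")
    return s.reindex(coords.index).astype(float)


def spin_test(
    map_a,
    map_b,
    coords: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    _chunk: int = 500,
) -> SpinResult:
    """Spin permutation test of the correlation between two unit maps.

    Parameters
    ----------
    map_a, map_b
        Per-unit values (Series or BiasMap) defined on ``coords.index``;
        ``map_a`` is the one rotated.
    coords
        Unit-sphere centroids with columns x, y, z, hemisphere.
    alternative
        ``greater`` (proportion of null correlations exceeding the observed,
        the default) or ``two-sided`` (on absolute values).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = _as_series(map_a, coords).to_numpy()
    b = _as_series(map_b, coords).to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("maps must not contain missing values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map: correlation undefined")

    xyz = coords[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(xyz, axis=1)
    if np.abs(norms - 1).max() > 1e-6:
        raise ValueError("coordinates must lie on the unit sphere")
    hemi = coords["hemisphere"].to_numpy()

    r_obs = float(stats.pearsonr(a, b)[0])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5917]))
    rotations = stats.special_ortho_group.rvs(3, size=n_perm, random_state=rng)
    if rotations.ndim == 2:
        rotations = rotations[None, :, :]

    hemi_groups = []
    for h in np.unique(hemi):
        idx = np.flatnonzero(hemi == h)
        hemi_groups.append((h, idx, xyz[idx]))

    null_r = np.empty(n_perm)
    bc = b - b.mean()
    bden = np.sqrt((bc**2).sum())
    for start in range(0, n_perm, _chunk):
        R = rotations[start:start + _chunk]
        k = R.shape[0]
        a_rot = np.empty((k, len(a)))
        for h, idx, pts in hemi_groups:
            Rh = R if h != "L" else _MIRROR @ R @ _MIRROR
            # rotated positions of this hemisphere's units, per permutation
            rotated = np.einsum("kij,nj->kni", Rh, pts)
            # each original unit takes the value of the nearest rotated unit
            dots = np.einsum("ni,kmi->knm", pts, rotated)
            nearest = dots.argmax(axis=2)
            a_rot[:, idx] = a[idx][nearest]
        ac = a_rot - a_rot.mean(axis=1, keepdims=True)
        aden = np.sqrt((ac**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            null_r[start:start + k] = (ac @ bc) / (aden * bden)
    null_r = np.nan_to_num(null_r, nan=0.0)

    if alternative == "greater":
        exceed = int((null_r >= r_obs).sum())
    else:
        exceed = int((np.abs(null_r) >= abs(r_obs)).sum())
    p = (exceed + 1) / (n_perm + 1)
    return SpinResult(r_observed=r_obs, n_perm=n_perm, p_value=float(p),
                      null_r=null_r, alternative=alternative)
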