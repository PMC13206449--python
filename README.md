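# tivbench

Benchmarking head-size adjustment methods for brain morphometry, with an
age + TIV matched gold standard.

## The problem

Male heads are on average ~14% larger than female heads (total intracranial
volume, TIV). Any sex comparison of regional brain measures — volumes,
surface area, cortical thickness, deformation-based morphometry (DBM) — is
therefore confounded by head size, and the field corrects for it in several
incompatible ways. Because regional structures scale *allometrically* with
the head, `VOI = α · TIV^β` with β typically below 1, corrections that assume
proportionality or linearity leave method-specific residual biases.

`tivbench` implements, end to end and fully testable without any restricted
data, the evaluation design in which:

1. a **matched sample** of male–female pairs with near-identical age and TIV
   serves as the gold standard (head-size confounding removed by design,
   not by modeling);
2. four corrections are applied to a **not-matched** sample —
   * proportions: `MOI_adj = MOI / TIV`
   * power-corrected proportions (PCP): `MOI_adj = MOI / TIV^b`, with `b`
     the OLS slope of `log MOI ~ 1 + log TIV`
   * residuals: `MOI_adj = MOI − b (TIV − TIV̄)`, with `b` from `MOI ~ 1 + TIV`
   * covariate: TIV as a regressor in the model itself;
3. per unit (region/vertex/voxel) a standardized trajectory model is fitted,
   `z(MOI_adj) ~ 1 + z(age) + sex + z(age):sex [+ z(TIV)]`, female as
   reference;
4. the corrected sex estimates are compared against the gold standard
   (Pearson r; regression slope, ideal 1; paired t and Cohen's d with
   BH-FDR), and the per-unit residual bias — the signed orthogonal distance
   of each (gold, corrected) pair from the identity line — is mapped and
   tested against the allometry (β) map with a spatial spin permutation
   test.

A synthetic-cohort generator reproduces the statistical structure such data
has in large population cohorts (sex-specific Gaussian TIV, allometric
power-law scaling with multiplicative noise, linear aging decline, optional
true sex effects beyond head size, metric variants including
template-normalized DBM), and emits the true per-unit parameters so every
stage has ground truth. A spherical icosphere mesh with an FWHM-parameterized
geodesic Gaussian smoother supports the vertexwise smoothing analyses.

## Worked example

```bash
python examples/04_method_ranking.py
```

prints (seed 1; 2,000 participants per sex, 60 regions, heterogeneous
allometry β ∈ [0.6, 1.1] and true sex effects beyond TIV):

```
matched pairs: 847

sex-estimate agreement with the matched gold standard (not-matched sample):
  none         r = 0.971   slope = 0.739   paired d = +4.56
  proportions  r = 0.967   slope = 0.832   paired d = -0.96
  pcp          r = 0.986   slope = 0.616   paired d = -0.04
  residuals    r = 0.987   slope = 0.606   paired d = -0.05
  covariate    r = 0.991   slope = 0.939   paired d = -0.28

bias map vs true allometry map (spin test, 1000 rotations):
  pcp          r = +0.653   p_spin = 0.001998
  residuals    r = +0.654   p_spin = 0.001998
  covariate    r = +0.252   p_spin = 0.02797
```

Reading: raw (`none`) estimates are strongly shifted toward male-larger
(paired d = +4.6) because TIV is uncorrected. PCP and residuals agree with
the gold standard in *ordering* (r ≈ 0.99) but systematically shrink the
effects (slope ≈ 0.6) — they absorb part of the true sex differences into
the fitted scaling coefficient — and the bias they leave behind follows the
allometry map (spin p ≈ 0.002). Adding TIV as a covariate is closest to the
ideal r = 1, slope = 1, with a much weaker allometric bias pattern.

The other examples (`examples/01…06`) walk through cohort simulation,
matching, the individual corrections, spin-test calibration and surface
smoothing. The same stages are scriptable from the shell via the `tivbench`
CLI (`simulate`, `match`, `subsample`, `adjust`, `fit`, `compare`, `bias`,
`spin`, `smooth`, `run-all`).

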