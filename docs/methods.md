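# Methods

## Generative model

Each synthetic participant has sex, an age in integer months (uniform over
45–82 years by default, independent of sex so that confounding is controlled
by *matching*, not by the generator; an optional offset shifts the male age
range by about a year, as seen in population cohorts), and a TIV drawn from a
sex-specific Gaussian truncated at zero (defaults: F 1,336,544 ± 103,197 mm³;
M 1,525,387 ± 119,265 mm³, the moments of a ~36k-participant population
imaging cohort).

Regional measures follow allometric power-law scaling with multiplicative
structure:

```
v_ij = α_j · TIV_i^{β_j} · (1 + s_j · age_c,i) · exp(γ_j · I[male_i]) · ε_ij
```

* `β_j` — per-unit allometric exponent, uniform on (0.6, 1.1) by default:
  most gray-matter structures scale hypometrically (β < 1), a few near or
  above isometry. The true exponents are emitted alongside the matrix;
  a simulation study needs ground truth even though observational data has
  none.
* `α_j` — scale constants, log-uniform on (0.01, 0.05); they only set units
  and cancel under the z-scoring used downstream.
* `s_j` — linear age slope as a fraction per decade, uniform on
  (−0.06, −0.02): a 2–6% decline per decade, which yields standardized age
  estimates around −0.2, the magnitude typical of regional volumes. `age_c`
  is age centered within the cohort, in decades. The linear factor is
  floored at a tiny positive value so the output is strictly positive even
  for pathological configurations; with default ranges the floor is never
  active (|age_c| < 2 decades, |s_j| ≤ 0.06).
* `γ_j` — true per-unit log sex effects beyond head size, Gaussian with SD
  `sex_effect_sd` (default 0). An optional correlation
  `sex_effect_beta_corr` couples `γ_j` to `β_j`; see *Benchmark
  configuration* below.
* `ε_ij` — log-normal with mean 1 and coefficient of variation `noise_cv`,
  default 0.20. This is the total residual inter-individual variability
  (biological plus measurement), chosen so that age+sex+TIV models reach
  adjusted R² ≈ 0.2 and unadjusted models ≈ 0.1, the regime observed for
  regional volumes in large cohorts. Noise is multiplicative to preserve
  positivity and to make the log-linear PCP model exactly correct at the
  generative level.

Metric variants: surface area uses the same form (different units);
cortical thickness replaces `β_j` by a single weak exponent (`ct_beta`,
default 0.1) since thickness is nearly head-size independent; DBM multiplies
the volume form by `tiv_ref / TIV`, modeling the linear normalization to a
template that precedes deformation estimation — for β = 1 the head-size
dependence cancels exactly, and for β < 1 it reverses sign, which is what
flips DBM sex estimates relative to native-space volumes.

One RNG stream per (config, seed), with per-stage sub-streams derived by
hashing stable stage labels; identical config + seed is bit-identical.

### What the generator does not emulate

No image-level processes (intensity, segmentation or registration error),
no spatial correlation of the noise across units (except what smoothing
introduces), no nonlinear aging, no site/scanner effects, no missingness
structure beyond missing-completely-at-random. Passing tests therefore show
that the *analysis machinery* behaves as designed under the stated
statistical structure — not that any particular empirical dataset satisfies
that structure.

## Matching

The gold standard pairs each male with a female whose age (months) and TIV
lie within a relative caliper of the male's values, by a greedy seeded scan:
split by sex, randomize both orders, claim the first feasible female per
male, drop unmatched males. Relative tolerance is applied to integer months
(the caliper is relative on both variables; an absolute month cap would be
an arbitrary second unit). Greedy first-fit is deliberately order-dependent
and makes no optimality claim; tests bound it by an exact bipartite-matching
oracle.

Two calipers are used:

* **0.02% (2e-4)** — the strict pair-validity caliper. At desk-scale cohort
  sizes (10³–10⁴ per sex) the expected number of feasible partners per male
  under the default TIV/age marginals is of order 0.01, so this caliper
  retains only tens of pairs: enough to verify pair quality, far too few to
  estimate per-unit trajectories.
* **2% (`presets.ANALYSIS_MATCH_TOLERANCE`)** — the caliper used to build
  the gold standard in simulation studies. It matches ~40% of males (the
  overlap mass of the two TIV distributions) while shrinking the between-sex
  TIV mean gap from ~14% to ~0.2%.

With a percent-scale caliper, first-fit inherits a systematic within-pair
gap from the sloping female TIV density (the chosen female tends to lie
below the male), which would re-confound the gold standard. The analysis
configurations therefore use `tie_break="nearest"`: among feasible females,
claim the one nearest in relative TIV. This reduces the mean within-pair gap
to ~0.2–0.3%, i.e. a residual shift of standardized sex estimates below
0.01.

The `not_matched` design is a simple per-sex random draw (the full cohort
is the target distribution). The `extreme` design draws from the cohort
minus the matched members — removing the mid-TIV overlap exaggerates the
sex gap — stratified on full-cohort age deciles so the age profile is
preserved without inventing a weighting scheme.

## Trajectory model

Per unit, OLS on `z(outcome) ~ 1 + z(age) + sex + z(age):sex [+ z(g)]`:

* all z-scores use the sample SD (ddof 1) and are recomputed **within each
  design sample**, the outcome *after* any value-transform correction —
  each subsample is an independent analysis;
* sex is an unscaled 0/1 indicator (female reference), so the sex
  coefficient is a standardized mean difference; z-scoring a binary factor
  would only rescale it by an arbitrary prevalence-dependent constant;
* the interaction is the product of z-scored age and the indicator, not
  re-scored;
* the global covariate (eq5), when present, is z-scored within the
  subsample like every other continuous variable;
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p predictors beside
  the intercept;
* units with zero outcome variance or too few observed rows are skipped and
  recorded, never imputed; missing entries drop that unit's rows only,
  while predictors stay z-scored on the full design sample (z-scoring is a
  sample-level convention).

Fits are batched (one shared design matrix, multi-column solve) and are
verified against statsmodels OLS coefficient-by-coefficient in the tests.

### Slope/exponent fitting sample

PCP exponents and residuals slopes are estimated per unit on the pooled
(both-sex) analysis sample — normalizing each group separately is known to
bias group comparisons, and pooling is the standard usage. When a subsample
is analyzed, the default fitting sample is that subsample (switchable via
`fitting_sample`), keeping each analysis self-contained.

## Evaluation statistics

* Pearson r and the OLS slope of **test on reference** (ideal slope 1; a
  slope below 1 is systematic shrinkage). The opposite direction is
  available via a flag; the reported default is fixed and documented
  because the two regressions are not interchangeable.
* Paired t over per-unit differences; paired Cohen's d = mean(diff)/sd(diff).
  All-zero differences return t = 0, p = 1, d = 0 rather than NaN.
* Benjamini–Hochberg FDR across the terms of one comparison report (the
  natural family here; implemented via statsmodels, verified against a
  hand-written step-up oracle).
* The partial-correlation control residualizes an adjusted outcome on the
  global variable within the design sample, re-z-scores, refits the base
  model and reports adjusted R²: if an adjustment injected head-size signal
  (dividing a nearly head-size-independent measure by TIV), the partialled
  R² collapses.

## Bias maps and the spin test

Residual bias per unit is the signed orthogonal distance of the point
(gold estimate, corrected estimate) from the identity line,
`(test − ref)/√2`; positive values mean the corrected estimate still leans
toward the male direction (undercorrection).

The spin test draws uniform random 3D rotations (scipy's special orthogonal
sampler), applies the mirrored rotation to the contralateral hemisphere,
reassigns each unit the value of its nearest rotated neighbor within its
hemisphere, and recomputes the map correlation. The empirical p is
one-sided — the proportion of null correlations *exceeding* the observed
one — with a +1 correction so p ∈ [1/(n+1), 1]; a two-sided variant is
available. Unit coordinates for synthetic parcellations are a Fibonacci
lattice on the unit sphere (no real parcellation is shipped), hemispheres
split by the sign of x. Calibration under independent smooth map pairs is
part of the acceptance suite (200 studies, 500 rotations each,
Kolmogorov–Smirnov uniformity check).

## Surface smoothing

The mesh is a subdivided icosahedron projected to the unit sphere
(subdivision n has 10·4ⁿ + 2 vertices). Distances are graph geodesics along
edges with arc-length weights, scaled by `mesh_scale` (default radius
100 mm, the order of a hemisphere); on a mesh this regular the shortest
path along edges overestimates the true geodesic by at most a few percent,
which is absorbed into the nominal FWHM. The kernel is Gaussian with
σ = FWHM/(2√(2 ln 2)), truncated at 3σ and renormalized; FWHM 0 is the
identity; missing values are excluded from numerator and denominator.
Note that at subdivision 3 the vertex spacing is ~14 mm, so FWHM ≤ 10 mm
lies inside the truncation radius of nothing but the vertex itself and acts
as the identity — the spread-vs-FWHM curve is flat there and rises beyond.
Units observed in fewer than 80% of participants are dropped before
modeling (`filter_units_by_missingness`).

## Benchmark configuration

`presets.headline_config` fixes the method-ranking study: 2,000 per sex, 60
units, β ∈ (0.6, 1.1), true sex effects with SD 0.08 on the log scale
(regional male/female differences up to ~±16%, giving gold-standard
standardized sex estimates spread ≈ 0.4–0.5, bidirectional), coupled to the
exponents with correlation −0.7. The coupling is a deliberate modeling
choice: with exchangeable sex effects the expected correlation between any
correction's bias map and the allometry map is exactly zero (the bias is an
odd function of the per-unit sex effect), whereas real morphometry shows
regional sex differences that co-vary spatially with allometric scaling.
The negative sign places female-larger effects in strongly allometric
regions, so the shrinkage bias of the scaling-based corrections (PCP,
residuals) aligns *positively* with the allometry map while the covariate
method's association stays weak — the qualitative pattern the benchmark is
designed to expose. Under this configuration the benchmark reproduces, on
synthetic data, the characteristic ordering: covariate r ≈ 0.99 and slope
≈ 0.94–0.97; PCP/residuals r ≈ 0.99 but slope ≈ 0.6 with mutually
near-identical estimates; proportions sign-reversal for hypometric units.

Problem sizes throughout the test and acceptance suites (5,000 per sex for
matching and centering checks, 2,000 per sex for the ranking study, 642
vertices for the smoothing study, 500–1,000 rotations per spin test, 100
replicates for exponent recovery) were chosen as the smallest sizes at
which the targeted properties are stable across seeds.

## Known limitations

* The greedy matcher is not optimal matching; its yield is bounded by the
  overlap of the two TIV distributions, and the `nearest` tie-break trades
  a little of the paper-trail simplicity of first-fit for unconfoundedness
  at desk scale.
* The spin test's nearest-neighbor reassignment duplicates some values and
  drops others; its null is approximate, which is why calibration is
  checked empirically rather than assumed.
* The geodesic Gaussian smoother approximates the iterative
  nearest-neighbor smoothers of surface pipelines; equivalence is
  qualitative, not numerical.
* Cortical thickness is modeled with a single global exponent; real
  thickness maps have regional structure the generator does not attempt.
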