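# File schemas

All tables are TSV with a single header line. Written and read by
`tivbench.io`; every file round-trips losslessly.

## cohort.tsv

| column | type | units | description |
|---|---|---|---|
| participant_id | str | — | unique id; generator uses `F000000…`/`M000000…` |
| sex | str | — | `F` or `M` |
| age_months | int | months | age at acquisition |
| tiv | float | mm³ | total intracranial volume |
| tcv | float | mm³ | optional: total cerebral volume |
| tsa | float | mm² | optional: total surface area |
| mct | float | mm | optional: mean cortical thickness |
| tiv_alt | float | mm³ | optional: second TIV source |

## measures_*.tsv (MeasureMatrix)

First column `participant_id`; one column per unit id (`u0000…` regions,
`v0…` vertices). Values in the metric's units (mm³ volume, mm² surface
area, mm thickness, unitless DBM). Missing entries are empty. Metric label
and smoothing FWHM are carried by the file name / reader arguments.

## unit_truth.tsv

| column | description |
|---|---|
| unit | unit id |
| alpha | true scale constant |
| beta | true allometric exponent |
| age_slope | true fraction-per-decade age slope |
| sex_effect | true log sex effect beyond head size |

## design_*.tsv (SampleDesign)

| column | description |
|---|---|
| participant_id | member id |
| matched_to | partner id for paired designs, empty otherwise |
| label | `matched`, `age_matched`, `not_matched`, `extreme` |
| tolerance | relative matching caliper (empty for draws) |

## estimates_*.tsv (TrajectoryEstimates, tidy)

| column | description |
|---|---|
| unit | unit id |
| term | `intercept`, `age`, `sex`, `age_sex`, `global` |
| estimate | standardized coefficient |
| se | standard error |
| p | two-sided p-value |
| adj_r2 | adjusted R² of the unit's model |
| n | sample size used |
| model | `eq1` (base) or `eq5` (global covariate) |
| sample | design label |
| method | correction method label |

## comparison_*.tsv (ComparisonReport)

Indexed by `term`: `r`, `slope`, `t`, `p_raw`, `cohens_d`, `n_units`,
`p_fdr` (BH across the report's terms).

## bias_*.tsv / unit maps

`unit`, `value` — signed orthogonal-distance bias (standardized-estimate
units) or any per-unit map.

## unit_coords.tsv

`unit`, `x`, `y`, `z` (unit sphere), `hemisphere` (`L`/`R`).

## spin_results.tsv

`method`, `r_observed`, `n_perm`, `p_value`, `null_mean`, `null_sd`,
`null_q95`.

## simulation_config.yaml / pipeline config

YAML mapping of `SimulationConfig` fields (see its docstring for units and
defaults); the pipeline config nests it under `simulation` plus
`match_tolerance`, `methods`, `global_var`, `terms`, `n_spin`, `out_dir`.

## Meshes

ASCII PLY (`element vertex` / `element face`, `vertex_indices` lists);
vertices on the unit sphere.
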