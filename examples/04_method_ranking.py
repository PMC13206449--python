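"""The headline benchmark: which correction reproduces the gold standard?

Fits the standardized trajectory model (z(value) ~ 1 + z(age) + sex +
z(age):sex [+ z(TIV)]) per region in the matched and not-matched samples and
compares the per-region sex estimates: Pearson r measures agreement, the
regression slope measures systematic shrinkage (ideal: r = 1, slope = 1).
"""

from tivbench import PipelineConfig, run_pipeline
from tivbench.presets import headline_config

cfg = PipelineConfig(simulation=headline_config(seed=1), n_spin=1000)
bundle = run_pipeline(cfg)

print(f"matched pairs: {bundle['designs']['matched'].n_pairs}\n")
print("sex-estimate agreement with the matched gold standard (not-matched sample):")
for method, rep in bundle["comparisons"].items():
    row = rep.table.loc["sex"]
    print(f"  {method:12s} r = {row['r']:.3f}   slope = {row['slope']:.3f}   "
          f"paired d = {row['cohens_d']:+.2f}")
print("\nbias map vs true allometry map (spin test, 1000 rotations):")
for method in ("pcp", "residuals", "covariate"):
    s = bundle["spins"][method]
    print(f"  {method:12s} r = {s.r_observed:+.3f}   p_spin = {s.p_value:.4g}")
print("\nAdding TIV as a covariate tracks the gold standard best (slope ~ 1);")
print("PCP/residuals agree in ordering (r ~ 0.99) but shrink effects (slope ~ 0.6),")
print("and their residual bias follows the allometry map far more strongly than")
print("the covariate method's.")
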