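"""Build the age+TIV matched gold standard and the comparison subsamples.

Matching removes head-size confounding by design: after pairing each male
with a female of near-identical age and TIV, the per-sex TIV means agree to
a fraction of a percent, while the 'extreme' sample (cohort minus matched
members) exaggerates the sex gap.
"""

from tivbench import build_subsample, match_by_age_tiv, simulate_cohort
from tivbench.presets import ANALYSIS_MATCH_TOLERANCE, cohort_config

cohort = simulate_cohort(cohort_config(seed=1, n_per_sex=2000))
matched = match_by_age_tiv(cohort, tolerance=ANALYSIS_MATCH_TOLERANCE,
                           seed=1, tie_break="nearest")
extreme = build_subsample(cohort, "extreme", matched.n_pairs, matched=matched, seed=1)

print(f"matched pairs: {matched.n_pairs} (caliper {ANALYSIS_MATCH_TOLERANCE:.0%})")
for label, design in [("full cohort", None), ("matched", matched), ("extreme", extreme)]:
    sub = cohort if design is None else cohort.loc[design.member_ids]
    means = sub.groupby("sex")["tiv"].mean()
    gap = 100 * (means["M"] - means["F"]) / means["F"]
    print(f"{label:12s} TIV means  F {means['F']:>12,.0f}  M {means['M']:>12,.0f}"
          f"   gap {gap:+.2f}%")
print("\nThe matched sample's near-zero gap is what makes it a gold standard")
print("for sex-difference estimation; the extreme sample widens the gap.")
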