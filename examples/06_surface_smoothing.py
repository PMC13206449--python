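"""Effect of surface smoothing on vertexwise sex estimates.

A coherent sex-effect field plus independent vertex noise on a
subdivision-3 icosphere (642 vertices, radius 100 mm): Gaussian geodesic
smoothing suppresses the noise, so standardized sex estimates grow in
magnitude - their spread across vertices increases with FWHM.
"""

import numpy as np
import pandas as pd

from tivbench import (SampleDesign, SimulationConfig, build_icosphere, fit_trajectory,
                      simulate_cohort, simulate_measures, smooth_vertex_data)

mesh = build_icosphere(3)
nv = mesh.n_vertices
cfg = SimulationConfig(n_per_sex=200, seed=3, n_units=nv, beta_range=(0.7, 0.9))
cohort = simulate_cohort(cfg)

rng = np.random.default_rng(3)
w = rng.standard_normal(3)
w /= np.linalg.norm(w)
params = pd.DataFrame({
    "alpha": np.full(nv, 0.02),
    "beta": rng.uniform(0.7, 0.9, nv),
    "age_slope": np.full(nv, -0.03),
    "sex_effect": 0.06 * (mesh.vertices @ w),   # smooth dipole field
}, index=pd.Index([f"v{i}" for i in range(nv)], name="unit"))
matrix, _ = simulate_measures(cohort, cfg, unit_params=params)
design = SampleDesign(label="all", member_ids=list(cohort.index))

print(f"{nv} vertices, {len(cohort)} participants")
print("FWHM (mm)   SD of standardized sex estimates across vertices")
for fwhm in (0, 5, 10, 15, 20, 25):
    sm = smooth_vertex_data(matrix, mesh, float(fwhm))
    est = fit_trajectory(sm, cohort, design)
    print(f"  {fwhm:4d}        {est.coef['sex'].std():.4f}")
print("\nThe spread is nondecreasing in FWHM: smoothing averages out vertex")
print("noise, inflating standardized effect sizes (and any residual bias).")
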