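"""End-to-end benchmark driver.

One call simulates a cohort and measure matrix, builds the four subsample
designs, applies every correction method, fits the standardized trajectory
models per (sample x method), compares everything against the matched gold
standard, maps residual biases and spins them against the true allometry map,
and writes the whole bundle as TSV plus a JSON manifest. Deterministic given
the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .adjustment import apply_adjustment
from .bias import bias_map, fibonacci_coordinates, spin_test
from .evaluation import compare_estimates, fit_summary
from .io import (write_cohort, write_coords, write_design, write_estimates,
                 write_map, write_matrix, write_sim_config)
from .presets import ANALYSIS_MATCH_TOLERANCE
from .sampling import build_subsample, match_by_age_tiv
from .simulate import SimulationConfig, simulate_cohort, simulate_measures
from .trajectory import fit_trajectory

logger = logging.getLogger("tivbench")

__all__ = ["PipelineConfig", "run_pipeline"]

_VALUE_METHODS = ("none", "proportions", "pcp", "residuals")


@dataclass
class PipelineConfig:
    """Configuration of one full benchmark run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    match_tolerance: float = ANALYSIS_MATCH_TOLERANCE
    methods: tuple = ("none", "proportions", "pcp", "residuals", "covariate")
    global_var: str = "tiv"
    terms: tuple = ("age", "sex", "age_sex")
    n_spin: int = 1000
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        bad = set(self.methods) - {"none", "proportions", "pcp", "residuals", "covariate"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation", {})
        for k in ("age_range", "beta_range", "alpha_range", "age_slope_range"):
            if k in sim and isinstance(sim[k], list):
                sim[k] = tuple(sim[k])
        for k in ("methods", "terms"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_yaml_text(self) -> str:
        d = dataclasses.asdict(self)

        def clean(x):
            if isinstance(x, tuple):
                return [clean(v) for v in x]
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            return x

        return yaml.safe_dump(clean(d), sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full benchmark; returns the artifact bundle as a dict.

    When ``config.out_dir`` is set, every artifact is also written as TSV
    (plus ``manifest.json``). Keys of the returned dict:

    ``cohort, matrix, truth, designs, adjusted, estimates, comparisons,
    summary, bias_maps, coords, spins``.
    """
    sim = config.simulation
    seed = sim.seed
    logger.info("simulating cohort (n_per_sex=%d, seed=%d)", sim.n_per_sex, seed)
    cohort = simulate_cohort(sim)
    matrix, truth = simulate_measures(cohort, sim)

    logger.info("building subsample designs (caliper %g)", config.match_tolerance)
    designs = {}
    designs["matched"] = match_by_age_tiv(cohort, tolerance=config.match_tolerance,
                                          seed=seed, tie_break="nearest")
    designs["age_matched"] = match_by_age_tiv(
        cohort, tolerance=config.match_tolerance, seed=seed,
        match_on=("age_months",), tie_break="nearest")
    n_sub = designs["matched"].n_pairs
    designs["not_matched"] = build_subsample(cohort, "not_matched", n_sub, seed=seed)
    designs["extreme"] = build_subsample(cohort, "extreme", n_sub,
                                         matched=designs["matched"], seed=seed)
    logger.info("matched pairs: %d", n_sub)

    adjusted = {}
    for method in config.methods:
        if method in ("none", "covariate"):
            continue
        adjusted[method], _ = apply_adjustment(matrix, cohort, method, config.global_var)

    estimates = {}
    for sample, design in designs.items():
        for method in config.methods:
            if method == "covariate":
                est = fit_trajectory(matrix, cohort, design, include_covariate=True,
                                     global_var=config.global_var, method_label="covariate")
            else:
                mat = matrix if method == "none" else adjusted[method]
                est = fit_trajectory(mat, cohort, design, method_label=method)
            estimates[(sample, method)] = est

    gold = estimates[("matched", "none")]
    comparisons = {}
    for method in config.methods:
        comparisons[method] = compare_estimates(gold, estimates[("not_matched", method)],
                                                terms=config.terms)

    summary = fit_summary([estimates[("not_matched", m)] for m in config.methods])

    coords = fibonacci_coordinates(len(truth), unit_ids=list(truth.index))
    bias_maps, spins = {}, {}
    beta_map = truth["beta"]
    for method in config.methods:
        bm = bias_map(gold, estimates[("not_matched", method)], term="sex", method=method)
        bias_maps[method] = bm
        if beta_map.std() > 0 and bm.values.std() > 0:
            spins[method] = spin_test(bm, beta_map, coords, n_perm=config.n_spin, seed=seed)

    bundle = {
        "cohort": cohort, "matrix": matrix, "truth": truth, "designs": designs,
        "adjusted": adjusted, "estimates": estimates, "comparisons": comparisons,
        "summary": summary, "bias_maps": bias_maps, "coords": coords, "spins": spins,
    }
    if config.out_dir is not None:
        _write_bundle(config, bundle)
    return bundle


def _write_bundle(config: PipelineConfig, bundle: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle["cohort"], out / "cohort.tsv")
    write_matrix(bundle["matrix"], out / "measures_raw.tsv")
    bundle["truth"].to_csv(out / "unit_truth.tsv", sep="\t", float_format="%.10g")
    write_sim_config(config.simulation, out / "simulation_config.yaml")
    for name, design in bundle["designs"].items():
        write_design(design, out / f"design_{name}.tsv")
    for method, mat in bundle["adjusted"].items():
        write_matrix(mat, out / f"measures_{method}.tsv")
    for (sample, method), est in bundle["estimates"].items():
        write_estimates(est, out / f"estimates_{sample}_{method}.tsv")
    for method, rep in bundle["comparisons"].items():
        rep.table.to_csv(out / f"comparison_{method}.tsv", sep="\t", float_format="%.10g")
    bundle["summary"].to_csv(out / "fit_summary.tsv", sep="\t", float_format="%.10g")
    write_coords(bundle["coords"], out / "unit_coords.tsv")
    for method, bm in bundle["bias_maps"].items():
        write_map(bm, out / f"bias_{method}_sex.tsv")
    spin_rows = [
        {"method": m, "r_observed": s.r_observed, "n_perm": s.n_perm,
         "p_value": s.p_value, **{f"null_{k}": v for k, v in s.null_summary().items()}}
        for m, s in bundle["spins"].items()
    ]
    if spin_rows:
        pd.DataFrame(spin_rows).to_csv(out / "spin_results.tsv", sep="\t",
                                       index=False, float_format="%.10g")

    cfg_text = config.to_yaml_text()
    manifest = {
        "tivbench_version": __version__,
        "seed": config.simulation.seed,
        "config": yaml.safe_load(cfg_text),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_matched_pairs": bundle["designs"]["matched"].n_pairs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
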