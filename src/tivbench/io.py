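"""Tabular I/O: TSV with one-line headers, YAML configs, ASCII PLY meshes.

Column schemas are documented in docs/schemas.md. Everything round-trips
losslessly through these readers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .bias import BiasMap
from .sampling import SampleDesign
from .simulate import MeasureMatrix, SimulationConfig
from .surface import SurfaceMesh
from .trajectory import TrajectoryEstimates

PathLike = Union[str, Path]


# -- cohort -----------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: PathLike) -> None:
    cohort.to_csv(path, sep="\t", index=True, float_format="%.6f")


def read_cohort(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="participant_id")
    df["age_months"] = df["age_months"].astype(int)
    return df


# -- measure matrices -------------------------------------------------------

def write_matrix(matrix: MeasureMatrix, path: PathLike) -> None:
    matrix.values.rename_axis("participant_id").to_csv(path, sep="\t", float_format="%.8g")


def read_matrix(path: PathLike, metric: str = "volume", smoothing_fwhm: float = 0.0) -> MeasureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="participant_id")
    return MeasureMatrix(values=df, metric=metric, smoothing_fwhm=smoothing_fwhm)


# -- sample designs ---------------------------------------------------------

def write_design(design: SampleDesign, path: PathLike) -> None:
    pairing = design.pairing or {}
    fem_of = {f: m for m, f in pairing.items()}
    rows = []
    for pid in design.member_ids:
        mate = pairing.get(pid, fem_of.get(pid, ""))
        rows.append({
            "participant_id": pid,
            "matched_to": mate,
            "label": design.label,
            "tolerance": "" if design.tolerance is None else repr(design.tolerance),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    label = df["label"].iloc[0]
    tol = df["tolerance"].iloc[0]
    members = list(df["participant_id"])
    pairing = None
    links = df[df["matched_to"] != ""]
    if len(links):
        # male ids start with M by generator convention; fall back to the
        # first id of each pair appearing in the file.
        pairing = {}
        seen = set()
        for a, b in zip(links["participant_id"], links["matched_to"]):
            if a in seen or b in seen:
                continue
            seen.update((a, b))
            male, female = (a, b) if a.startswith("M") else (b, a)
            pairing[male] = female
    return SampleDesign(label=label, member_ids=members, pairing=pairing,
                        tolerance=None if tol == "" else float(tol))


# -- trajectory estimates ---------------------------------------------------

def write_estimates(est: TrajectoryEstimates, path: PathLike) -> None:
    est.tidy().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_estimates(path: PathLike) -> TrajectoryEstimates:
    df = pd.read_csv(path, sep="\t")
    coef = df.pivot(index="unit", columns="term", values="estimate")
    se = df.pivot(index="unit", columns="term", values="se")
    p = df.pivot(index="unit", columns="term", values="p")
    terms = [t for t in ("intercept", "age", "sex", "age_sex", "global") if t in coef.columns]
    adj = df.drop_duplicates("unit").set_index("unit")["adj_r2"]
    first = df.iloc[0]
    return TrajectoryEstimates(
        coef=coef[terms], se=se[terms], pvalues=p[terms], adj_r2=adj,
        n=int(first["n"]), model=str(first["model"]),
        sample=str(first["sample"]), method=str(first["method"]),
    )


# -- per-unit maps and coordinates ------------------------------------------

def write_map(values: Union[pd.Series, BiasMap], path: PathLike) -> None:
    s = values.values if isinstance(values, BiasMap) else values
    s.rename("value").rename_axis("unit").to_csv(path, sep="\t", float_format="%.10g")


def read_map(path: PathLike) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="unit")["value"]


def write_coords(coords: pd.DataFrame, path: PathLike) -> None:
    coords.to_csv(path, sep="\t", float_format="%.10g")


def read_coords(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="unit")


# -- meshes -----------------------------------------------------------------

def write_mesh_ply(mesh: SurfaceMesh, path: PathLike) -> None:
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x", "property float y", "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_ply(path: PathLike) -> SurfaceMesh:
    text = Path(path).read_text().splitlines()
    nv = nf = None
    for i, line in enumerate(text):
        if line.startswith("element vertex"):
            nv = int(line.split()[-1])
        elif line.startswith("element face"):
            nf = int(line.split()[-1])
        elif line == "end_header":
            body = text[i + 1:]
            break
    verts = np.array([[float(x) for x in body[k].split()] for k in range(nv)])
    faces = np.array([[int(x) for x in body[nv + k].split()[1:]] for k in range(nf)])
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(vertices=verts, faces=faces)


# -- configuration ----------------------------------------------------------

def write_sim_config(config: SimulationConfig, path: PathLike) -> None:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_sim_config(path: PathLike) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("age_range", "beta_range", "alpha_range", "age_slope_range"):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return SimulationConfig(**d)
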