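"""Spherical meshes and FWHM-parameterized surface smoothing.

Vertexwise analyses need a neighborhood structure and a smoother whose
bandwidth is expressed in mm full-width-at-half-maximum, as surface pipelines
report it. The mesh is a subdivided icosahedron projected to the unit sphere;
distances between vertices are graph geodesics (shortest paths along edges,
arc-length weighted), a good approximation of true geodesics on a mesh this
regular. ``mesh_scale`` converts unit-sphere distances to mm; the default
radius of 100 mm is of the order of a hemisphere, so FWHM values of 0-25 mm
are physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .simulate import MeasureMatrix

__all__ = ["SurfaceMesh", "build_icosphere", "smooth_vertex_data", "filter_units_by_missingness"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated sphere: vertices on the unit sphere plus faces."""

    vertices: np.ndarray  # (n, 3), unit norm
    faces: np.ndarray     # (m, 3) vertex index triples

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vertices, axis=1)
        if np.abs(norms - 1).max() > 1e-6:
            raise ValueError("mesh vertices must lie on the unit sphere")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted index pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        """Great-circle arc length of each edge (unit-sphere radians)."""
        a = self.vertices[self.edges[:, 0]]
        b = self.vertices[self.edges[:, 1]]
        cos = np.clip((a * b).sum(axis=1), -1.0, 1.0)
        return np.arccos(cos)

    def geodesic_distances(self, mesh_scale: float = 100.0, limit: float = np.inf) -> np.ndarray:
        """All-pairs graph-geodesic distances in mm (inf beyond ``limit``)."""
        w = self.edge_lengths() * mesh_scale
        if (w <= 0).any():
            raise ValueError("degenerate mesh: zero-length edge")
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_vertices
        graph = coo_matrix((np.concatenate([w, w]),
                            (np.concatenate([i, j]), np.concatenate([j, i]))),
                           shape=(n, n)).tocsr()
        return dijkstra(graph, directed=False, limit=limit)


def build_icosphere(subdivisions: int) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to the sphere.

    Vertex count is ``10 * 4**subdivisions + 2``.
    """
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions}")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(m.vertices, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SurfaceMesh(vertices=v, faces=np.asarray(m.faces, dtype=int))


def smooth_vertex_data(
    matrix: MeasureMatrix,
    mesh: SurfaceMesh,
    fwhm: float,
    mesh_scale: float = 100.0,
) -> MeasureMatrix:
    """Geodesic Gaussian smoothing of vertexwise data.

    Per participant, ``value_i <- sum_j w_ij v_j / sum_j w_ij`` with
    ``w_ij = exp(-d_ij^2 / (2 sigma^2))``, ``sigma = fwhm / (2 sqrt(2 ln 2))``
    and ``d_ij`` the graph-geodesic distance in mm, truncated at 3 sigma
    (weights renormalized). ``fwhm = 0`` is the identity. Missing entries are
    excluded from both sums; a vertex with no observed neighbor inside the
    kernel stays missing.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if matrix.values.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"matrix has {matrix.values.shape[1]} columns but mesh has {mesh.n_vertices} vertices"
        )
    if fwhm == 0:
        return matrix.copy_with(matrix.values.copy(), smoothing_fwhm=0.0)

    sigma = fwhm * _FWHM_TO_SIGMA
    D = mesh.geodesic_distances(mesh_scale=mesh_scale, limit=3.0 * sigma)
    K = np.zeros_like(D)
    inside = np.isfinite(D)
    K[inside] = np.exp(-D[inside] ** 2 / (2.0 * sigma**2))

    V = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(V)
    num = np.where(observed, V, 0.0) @ K.T
    den = observed.astype(float) @ K.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan

    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(frame, smoothing_fwhm=float(fwhm))


def filter_units_by_missingness(matrix: MeasureMatrix, max_missing: float = 0.2) -> MeasureMatrix:
    """Drop units observed in less than ``1 - max_missing`` of participants.

    The default keeps units with at least 80% non-missing values, the usual
    vertex filter before modeling.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = matrix.missing_fraction()
    keep = frac.index[frac <= max_missing]
    return matrix.copy_with(matrix.values[keep].copy())
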