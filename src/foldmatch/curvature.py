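"""Discrete curvature estimation and longitudinal folding-change measures.

Per-vertex principal curvatures k1 >= k2 (1/mm) are estimated by fitting a
quadric height function over a ring neighborhood in the local tangent
frame.  From them: mean curvature M = (k1 + k2)/2, Gaussian curvature
G = k1*k2 and total curvature T = k1^2 + k2^2.  Sign convention follows
the anatomy: outward-convex regions (gyri) have positive mean curvature,
concave grooves (sulci) negative.

Longitudinal change is always expressed on the early mesh, through a
late->early pull-back along the vertex correspondence.  Curvatures are
first normalized for overall brain growth by the cube root of the
enclosed-volume ratio, so that a pure uniform expansion produces zero
change; the bending-energy change tracks the per-vertex change of the
integrand of E = integral (k1^2 + k2^2) dA, with local vertex areas as the
measure, so folding work is separated from mere area growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .cpd import Correspondence
from .mesh import TriangleMesh, vertex_areas

__all__ = [
    "CurvatureField",
    "ChangeMap",
    "principal_curvatures",
    "volume_normalize",
    "map_scalar",
    "curvature_change",
    "local_area_change",
    "bending_energy_change",
    "total_bending_energy",
]


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures and their invariants (1/mm)."""

    k1: np.ndarray
    k2: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(self.k1 >= self.k2 - 1e-12)

    @property
    def mean(self) -> np.ndarray:
        """M = (k1 + k2) / 2."""
        return 0.5 * (self.k1 + self.k2)

    @property
    def gaussian(self) -> np.ndarray:
        """G = k1 * k2."""
        return self.k1 * self.k2

    @property
    def total(self) -> np.ndarray:
        """T = k1^2 + k2^2 = 4 M^2 - 2 G."""
        return self.k1 ** 2 + self.k2 ** 2


@dataclass
class ChangeMap:
    """Longitudinal per-vertex changes, on the early mesh."""

    delta_mean: np.ndarray            # volume-normalized, 1/mm
    delta_gaussian: np.ndarray        # volume-normalized, 1/mm^2
    area_change: np.ndarray           # dimensionless ratio, > 0
    bending_energy_change: np.ndarray # dimensionless (mm^2 * mm^-2)

    def __post_init__(self) -> None:
        assert np.all(self.area_change > 0)


def _ring_neighborhoods(mesh: TriangleMesh, ring: int) -> sp.csr_matrix:
    """Boolean reachability within ``ring`` edge hops (excluding self)."""
    adj = mesh.vertex_adjacency().astype(bool)
    reach = adj.copy()
    power = adj
    for _ in range(ring - 1):
        power = (power @ adj).astype(bool)
        reach = (reach + power).astype(bool)
    reach = sp.lil_matrix(reach)
    reach.setdiag(False)
    return reach.tocsr()


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Outward vertex normals from area-weighted face normals.

    Assumes the mesh is consistently oriented with outward-facing triangles
    (the convention of all meshes produced and read by this package).
    """
    v, t = mesh.vertices, mesh.triangles
    fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])  # 2*area weighted
    out = np.zeros_like(v)
    for c in range(3):
        np.add.at(out, t[:, c], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(norms, 1e-300)


def principal_curvatures(mesh: TriangleMesh, ring: int = 2) -> CurvatureField:
    """Quadric-fit principal curvatures over ring neighborhoods.

    For each vertex, neighbor offsets are expressed in the local frame
    (t1, t2, n) and a full quadric h(u, v) = a u^2 + b uv + c v^2 + d u + e v
    is fitted by least squares; k1 >= k2 are the eigenvalues of the shape
    operator of the fit.  A rank-deficient neighborhood triggers one ring
    enlargement before failing.
    """
    if ring < 1:
        raise ValueError("ring must be >= 1")
    normals = vertex_normals(mesh)
    neigh = _ring_neighborhoods(mesh, ring)
    v = mesh.vertices
    n_vert = mesh.n_vertices
    k1 = np.zeros(n_vert)
    k2 = np.zeros(n_vert)
    indptr, indices = neigh.indptr, neigh.indices
    wide = None
    for i in range(n_vert):
        nb = indices[indptr[i]: indptr[i + 1]]
        ks = _fit_vertex(v, normals, i, nb)
        if ks is None:
            if wide is None:
                wide = _ring_neighborhoods(mesh, ring + 1)
            nb = wide.indices[wide.indptr[i]: wide.indptr[i + 1]]
            ks = _fit_vertex(v, normals, i, nb)
            if ks is None:
                raise RuntimeError(
                    f"rank-deficient curvature neighborhood at vertex {i}"
                )
        k1[i], k2[i] = ks
    return CurvatureField(k1, k2)


def _fit_vertex(v: np.ndarray, normals: np.ndarray, i: int,
                nb: np.ndarray) -> tuple[float, float] | None:
    if len(nb) < 5:
        return None
    n = normals[i]
    # orthonormal tangent frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    offsets = v[nb] - v[i]
    u = offsets @ t1
    w = offsets @ t2
    h = offsets @ n
    design = np.column_stack([u * u, u * w, w * w, u, w])
    coef, _, rank, _ = np.linalg.lstsq(design, h, rcond=None)
    if rank < 5:
        return None
    a, b, c, d, e = coef
    # first/second fundamental forms of the graph z = h(u, v) at the origin
    denom = np.sqrt(1.0 + d * d + e * e)
    form1 = np.array([[1.0 + d * d, d * e], [d * e, 1.0 + e * e]])
    form2 = np.array([[2.0 * a, b], [b, 2.0 * c]]) / denom
    shape_op = np.linalg.solve(form1, form2)
    eigs = np.linalg.eigvals(shape_op).real
    # height h is measured along the outward normal: convex-outward caps
    # have h < 0 there, so flip sign to make gyri positive
    eigs = -eigs
    return float(eigs.max()), float(eigs.min())


def volume_normalize(values: np.ndarray, vol_subject: float,
                     vol_reference: float, power: float = 1.0) -> np.ndarray:
    """Correct curvature for overall brain size.

    Curvature has units of inverse length, so rescaling the subject to the
    reference volume multiplies it by the cube-root volume ratio
    (vol_subject / vol_reference)^(1/3); a uniformly scaled copy of a mesh
    then has identical normalized curvature.  ``power`` is the inverse-
    length order of the quantity: 1 for principal/mean curvature (1/mm),
    2 for Gaussian curvature (1/mm^2).
    """
    if vol_subject <= 0 or vol_reference <= 0:
        raise ValueError("volumes must be positive")
    return np.asarray(values) * (vol_subject / vol_reference) ** (power / 3.0)


def map_scalar(corr: Correspondence, values_on_late: np.ndarray) -> np.ndarray:
    """Pull a per-vertex scalar back along an early->late correspondence:
    early vertex v receives the late value at corr(v)."""
    return np.asarray(values_on_late)[corr.map]


def curvature_change(
    field_early: CurvatureField,
    field_late: CurvatureField,
    corr: Correspondence,
    vol_early: float,
    vol_late: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-normalized (delta_M, delta_G) on the early mesh.

    Both curvature fields are normalized against the subject's mean
    enclosed volume of the two time points before differencing, so uniform
    growth contributes nothing.
    """
    vol_ref = 0.5 * (vol_early + vol_late)
    m_early = volume_normalize(field_early.mean, vol_early, vol_ref)
    m_late = volume_normalize(field_late.mean, vol_late, vol_ref)
    g_early = volume_normalize(field_early.gaussian, vol_early, vol_ref, power=2)
    g_late = volume_normalize(field_late.gaussian, vol_late, vol_ref, power=2)
    delta_m = map_scalar(corr, m_late) - m_early
    delta_g = map_scalar(corr, g_late) - g_early
    return delta_m, delta_g


def _one_ring_smooth(mesh: TriangleMesh, values: np.ndarray) -> np.ndarray:
    adj = mesh.vertex_adjacency().astype(np.float64)
    adj = adj + sp.eye(mesh.n_vertices)
    counts = np.asarray(adj.sum(axis=1)).ravel()
    return np.asarray(adj @ values).ravel() / counts


def local_area_change(
    mesh_early: TriangleMesh,
    mesh_late: TriangleMesh,
    corr: Correspondence,
    smooth: bool = True,
) -> np.ndarray:
    """Per-early-vertex area expansion ratio a_late(corr(v)) / a_early(v),
    smoothed by one ring of uniform neighborhood averaging."""
    a_early = vertex_areas(mesh_early)
    a_late = vertex_areas(mesh_late)
    if np.any(a_early <= 0):
        raise ValueError("zero early vertex area")
    ratio = a_late[corr.map] / a_early
    if smooth:
        ratio = _one_ring_smooth(mesh_early, ratio)
    return ratio


def bending_energy_change(
    field_early: CurvatureField,
    field_late: CurvatureField,
    corr: Correspondence,
    area_change: np.ndarray,
    mesh_early: TriangleMesh,
    ordering: str = "energy",
) -> np.ndarray:
    """Per-early-vertex change of the bending energy E = int (k1^2+k2^2) dA.

    Default ``ordering="energy"``: the late total curvature at the matched
    vertex is re-expressed over the early vertex area via the local area
    ratio (a_late = ratio * a_early) and the early contribution subtracted:

        dE(v) = T_late(c(v)) * ratio(v) * a_early(v) - T_early(v) * a_early(v)

    which is exactly the change in the discrete energy integrand, vanishes
    in total between spheres of any radii (total bending energy of a
    sphere is the scale-invariant 8*pi), and is positive where folding work
    (gyrification) is done.  ``ordering="divide"`` applies the alternative
    reading in which the late total curvature is divided by the local area
    change before the pull-back.
    """
    a_early = vertex_areas(mesh_early)
    t_late = map_scalar(corr, field_late.total)
    if ordering == "energy":
        return (t_late * area_change - field_early.total) * a_early
    if ordering == "divide":
        return (t_late / area_change - field_early.total) * a_early
    raise ValueError("ordering must be 'energy' or 'divide'")


def total_bending_energy(mesh: TriangleMesh, field: CurvatureField) -> float:
    """Discrete E = sum_v T(v) * vertex_area(v); 8*pi for any sphere."""
    return float((field.total * vertex_areas(mesh)).sum())
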