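"""Triangle-mesh data model, standard-format I/O, and basic surface geometry.

The analysis operates on closed triangle meshes of the white–grey matter
boundary, one per brain region, hemisphere and scan.  Vertices are in mm.
All indices are 0-based internally; file formats keep their native
conventions at the I/O boundary.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TriangleMesh",
    "SubjectRecord",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "surface_area",
    "enclosed_volume",
    "vertex_areas",
    "largest_component",
    "parse_subject_table",
    "parse_weeks_days",
]

_MIN_TRIANGLE_AREA = 1e-12  # mm^2


class MeshValidationError(ValueError):
    """A mesh violates a structural invariant (bad indices, degenerate
    triangles, open surface where a closed one is required, ...)."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    triangles : (M, 3) int array of vertex indices
    region_label : optional region name, e.g. ``"PFC-left"``
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region_label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be an (M, 3) array")
        if len(self.vertices) == 0 or len(self.triangles) == 0:
            raise MeshValidationError("mesh has no vertices or no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            bad = np.where(
                (self.triangles < 0) | (self.triangles >= len(self.vertices))
            )[0]
            raise MeshValidationError(
                f"triangles reference out-of-range vertex indices "
                f"(triangle rows {bad[:10].tolist()})"
            )
        same = (
            (self.triangles[:, 0] == self.triangles[:, 1])
            | (self.triangles[:, 1] == self.triangles[:, 2])
            | (self.triangles[:, 0] == self.triangles[:, 2])
        )
        if same.any():
            raise MeshValidationError(
                f"triangles with repeated vertices: {np.where(same)[0][:10].tolist()}"
            )
        areas = self.triangle_areas()
        degenerate = np.where(areas <= _MIN_TRIANGLE_AREA)[0]
        if len(degenerate):
            raise MeshValidationError(
                f"zero-area triangles at rows {degenerate[:10].tolist()}"
            )

    # -- derived quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        """Area of each triangle (mm^2)."""
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with i < j."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one triangle (empty for closed meshes)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def vertex_adjacency(self) -> csr_matrix:
        """Sparse symmetric boolean vertex adjacency matrix."""
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e), dtype=np.int8)
        a = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    def diameter(self) -> float:
        """Length of the bounding-box diagonal (mm); a cheap size scale."""
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.triangles.copy(), self.region_label
        )


@dataclass
class SubjectRecord:
    """One infant's study metadata: gestational age at birth and equivalent
    gestational age (EGA) at the two scans, all in decimal weeks."""

    subject_id: str
    ga_birth: float
    ega_scan1: float
    ega_scan2: float
    qc_scan1: str = ""
    qc_scan2: str = ""
    volume_scan1_mm3: float | None = None
    volume_scan2_mm3: float | None = None

    def __post_init__(self) -> None:
        if not (self.ga_birth < self.ega_scan1 < self.ega_scan2):
            raise ValueError(
                f"{self.subject_id}: ages must satisfy birth < scan1 < scan2, "
                f"got {self.ga_birth}, {self.ega_scan1}, {self.ega_scan2}"
            )


# -- I/O ----------------------------------------------------------------------

_FORMATS = ("vtk", "ply", "off", "stl")


def _format_from_path(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from extension {path.suffix!r}")
    return ext


def read_mesh(path: str | Path, fmt: str = "auto") -> TriangleMesh:
    """Read a triangle mesh from VTK legacy polydata, PLY, OFF or STL.

    Vertex order is preserved as stored in the file, except for STL, which
    stores unindexed facets: coincident facet corners are merged there.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = _format_from_path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if fmt == "vtk":
        vertices, triangles = _read_vtk_legacy(path)
    else:
        tm = trimesh.load(str(path), file_type=fmt, process=False)
        if not isinstance(tm, trimesh.Trimesh):
            raise MeshValidationError(f"{path}: file does not contain a triangle mesh")
        vertices = np.asarray(tm.vertices, dtype=np.float64)
        triangles = np.asarray(tm.faces, dtype=np.int64)
        if fmt == "stl":
            # STL has no shared vertices; merge exact duplicates.
            vertices, inverse = np.unique(
                vertices.round(decimals=8), axis=0, return_inverse=True
            )
            triangles = inverse[triangles]
    return TriangleMesh(vertices, triangles, region_label=path.stem)


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str = "auto",
               point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh; ``point_data`` (per-vertex scalar arrays) is supported
    for the VTK legacy format only."""
    path = Path(path)
    if fmt == "auto":
        fmt = _format_from_path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if fmt == "vtk":
        _write_vtk_legacy(mesh, path, point_data or {})
        return
    if point_data:
        raise ValueError("per-vertex scalar arrays require the vtk format")
    mesh.to_trimesh().export(str(path), file_type=fmt)


def _read_vtk_legacy(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal legacy-VTK ASCII POLYDATA reader (POINTS + POLYGONS)."""
    text = Path(path).read_text()
    tokens = text.split()
    upper = [t.upper() for t in tokens]
    if "POLYDATA" not in upper:
        raise MeshValidationError(f"{path}: not a VTK POLYDATA file")
    try:
        i = upper.index("POINTS")
        n_pts = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=np.float64)
        vertices = coords.reshape(n_pts, 3)
        j = upper.index("POLYGONS")
        n_poly = int(tokens[j + 1])
        k = j + 3
        triangles = []
        # OFFSETS/CONNECTIVITY layout (VTK >= 5.1) or classic count-prefixed
        if upper[k] == "OFFSETS":
            dtype_tok = 1  # OFFSETS <dtype>
            offs = np.array(tokens[k + 1 + dtype_tok : k + 1 + dtype_tok + n_poly],
                            dtype=np.int64)
            k2 = upper.index("CONNECTIVITY")
            conn = np.array(tokens[k2 + 2 : k2 + 2 + int(offs[-1])], dtype=np.int64)
            for a, b in zip(offs[:-1], offs[1:]):
                poly = conn[a:b]
                for s in range(1, len(poly) - 1):  # fan-triangulate
                    triangles.append((poly[0], poly[s], poly[s + 1]))
        else:
            for _ in range(n_poly):
                cnt = int(tokens[k]); k += 1
                poly = [int(tokens[k + s]) for s in range(cnt)]; k += cnt
                for s in range(1, cnt - 1):
                    triangles.append((poly[0], poly[s], poly[s + 1]))
    except (ValueError, IndexError) as exc:
        raise MeshValidationError(f"{path}: malformed VTK polydata ({exc})") from exc
    return vertices, np.array(triangles, dtype=np.int64)


def _write_vtk_legacy(mesh: TriangleMesh, path: Path,
                      point_data: dict[str, np.ndarray]) -> None:
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"{mesh.region_label or 'surface'}\n")
    buf.write("ASCII\nDATASET POLYDATA\n")
    buf.write(f"POINTS {mesh.n_vertices} float\n")
    np.savetxt(buf, mesh.vertices, fmt="%.9g")
    m = mesh.n_triangles
    buf.write(f"POLYGONS {m} {4 * m}\n")
    np.savetxt(
        buf,
        np.column_stack([np.full(m, 3, dtype=np.int64), mesh.triangles]),
        fmt="%d",
    )
    if point_data:
        buf.write(f"POINT_DATA {mesh.n_vertices}\n")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=np.float64).ravel()
            if len(values) != mesh.n_vertices:
                raise ValueError(f"scalar array {name!r} has wrong length")
            safe = re.sub(r"\s+", "_", name)
            buf.write(f"SCALARS {safe} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(buf, values, fmt="%.9g")
    Path(path).write_text(buf.getvalue())


# -- geometry -----------------------------------------------------------------

def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area, the sum of the triangle areas (mm^2)."""
    return float(mesh.triangle_areas().sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume enclosed by a closed, consistently oriented surface (mm^3).

    Computed with the divergence theorem as the sum of signed tetrahedron
    volumes against the origin.  If the orientation points inward the signed
    volume is negative; the absolute value is returned (a warning is issued).
    """
    boundary = mesh.boundary_edges()
    if len(boundary):
        raise MeshValidationError(
            f"enclosed_volume requires a closed surface; {len(boundary)} "
            f"boundary edges, e.g. {boundary[:5].tolist()}"
        )
    v = mesh.vertices
    t = mesh.triangles
    signed = np.einsum(
        "ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])
    ).sum() / 6.0
    if signed < 0:
        warnings.warn("mesh orientation is inward; returning |signed volume|")
    return float(abs(signed))


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex area by the barycentric one-third rule (mm^2).

    Each vertex receives one third of the area of every incident triangle,
    so the values sum exactly to ``surface_area``.
    """
    areas = mesh.triangle_areas()
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    if np.any(out == 0):
        warnings.warn("isolated vertices present (zero vertex area)")
    return out


def largest_component(mesh: TriangleMesh) -> tuple[TriangleMesh, np.ndarray]:
    """Sub-mesh of the connected component with the most vertices.

    Returns the compacted sub-mesh and the array of original vertex indices
    (new index ``i`` corresponds to original index ``index_map[i]``).  Ties
    in vertex count are broken by total component area.
    """
    n_comp, labels = connected_components(mesh.vertex_adjacency(), directed=False)
    if n_comp == 1:
        return mesh.copy(), np.arange(mesh.n_vertices)
    areas = mesh.triangle_areas()
    tri_label = labels[mesh.triangles[:, 0]]
    counts = np.bincount(labels, minlength=n_comp)
    comp_area = np.bincount(tri_label, weights=areas, minlength=n_comp)
    # primary key vertex count, secondary key area; deterministic
    order = np.lexsort((-comp_area, -counts))
    best = order[0]
    keep = np.where(labels == best)[0]
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    tri = mesh.triangles[tri_label == best]
    sub = TriangleMesh(mesh.vertices[keep], remap[tri], mesh.region_label)
    return sub, keep


# -- subject metadata ---------------------------------------------------------

_WD_RE = re.compile(r"^\s*(\d+)\s*(?:\+\s*(\d+)\s*)?$")


def parse_weeks_days(text: str) -> float:
    """Parse an age given as ``"W + D"``, ``"W"`` or decimal weeks."""
    m = _WD_RE.match(str(text))
    if not m:
        try:
            return float(text)
        except (TypeError, ValueError):
            pass
        raise ValueError(f"cannot parse age {text!r} (expected 'W' or 'W + D')")
    weeks = int(m.group(1))
    days = int(m.group(2) or 0)
    if days >= 7:
        raise ValueError(f"invalid age {text!r}: days must be < 7")
    return weeks + days / 7.0


def parse_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata table (CSV or TSV with a header).

    Required columns: subject_id, ga_birth, ega_scan1, ega_scan2.  Optional:
    qc1, qc2, volume_scan1_mm3, volume_scan2_mm3.  Ages may be decimal weeks
    or "W + D" strings.
    """
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["subject_id", "ga_birth", "ega_scan1", "ega_scan2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            rec = SubjectRecord(
                subject_id=d["subject_id"].strip(),
                ga_birth=parse_weeks_days(d["ga_birth"]),
                ega_scan1=parse_weeks_days(d["ega_scan1"]),
                ega_scan2=parse_weeks_days(d["ega_scan2"]),
                qc_scan1=d.get("qc1", ""),
                qc_scan2=d.get("qc2", ""),
                volume_scan1_mm3=float(d["volume_scan1_mm3"])
                if d.get("volume_scan1_mm3") else None,
                volume_scan2_mm3=float(d["volume_scan2_mm3"])
                if d.get("volume_scan2_mm3") else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
        records.append(rec)
    return records
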