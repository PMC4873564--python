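"""Synthetic longitudinal cohorts of folding closed surfaces.

No neonatal MRI meshes are publicly deposited, so validation runs on
generated genus-0 surfaces that reproduce the statistical structure of the
study data: between the two scans the surface grows (area increasing
linearly with equivalent gestational age) and gains folding, with the
added folds confined to designated patches.  A surface is an icosphere
whose vertices are displaced radially by a sum of real spherical
harmonics:

    x_i = (R + f_base(d_i) + f_added(d_i) * taper(d_i) + noise) * d_i

Low-degree harmonics shared by both ages play the role of primary folds;
high-degree harmonics present only at the late age play the role of
secondary/tertiary folds emerging over the scan interval.  Growth is a
uniform radial scale (base folds scale with it), deliberately the simplest
model whose effect the volume normalization must remove, leaving the
patch-confined added folds as the only true signal.  Both meshes share the
icosphere parameterization, so the ground-truth correspondence is the
identity on vertex indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .cpd import Correspondence
from .mesh import SubjectRecord, TriangleMesh

__all__ = [
    "FoldingSpec",
    "generate_longitudinal_pair",
    "generate_cohort",
    "fixture_suite",
    "icosphere",
    "real_sph_harm",
    "DEFAULT_AGE_SCHEDULE",
    "STUDY_COHORT_TABLE",
]

# Nine-subject two-scan design used throughout: gestational age at birth
# and equivalent gestational ages at the two scans, in (weeks, days).
STUDY_COHORT_TABLE = [
    # id, GA birth, EGA scan 1, EGA scan 2, QC scan 1, QC scan 2
    ("a", "26 + 1", "33 + 1", "40 + 1", "Slight T1 motion", "Good"),
    ("b", "25 + 1", "31 + 3", "42", "Good", "Good"),
    ("c", "25 + 1", "31", "42", "Good", "Good"),
    ("d", "27 + 1", "30 + 6", "46 + 2", "Slight T1 motion", "Good"),
    ("e", "27 + 1", "29 + 6", "46 + 2", "Good", "Good"),
    ("f", "26 + 2", "31 + 6", "40 + 2", "Good", "Good"),
    ("g", "29 + 1", "31 + 1", "38 + 3", "Good", "Good"),
    ("h", "29 + 2", "32 + 4", "38 + 6", "Slight T1 motion", "Good"),
    ("i", "26", "33", "41", "Good", "Good"),
]

from .mesh import parse_weeks_days as _pwd

DEFAULT_AGE_SCHEDULE = [
    (_pwd(row[2]), _pwd(row[3])) for row in STUDY_COHORT_TABLE
]


@dataclass
class FoldingSpec:
    """Parameters of one synthetic longitudinal surface pair.

    Amplitudes are in mm; harmonics are (degree, order, amplitude) of real
    spherical harmonics.  ``patches`` are spherical caps (unit center
    direction, angular radius rad) to which the late-only harmonics are
    confined, with a smooth cosine taper over the outer 20% of each cap.
    """

    base_radius_early: float = 30.0
    base_radius_late: float = 40.0
    base_harmonics: list = field(default_factory=lambda: [
        (2, 1, 1.6), (3, 0, 1.3), (3, -2, 1.4), (4, 2, 1.2),
        (5, 1, 1.0), (5, -3, 1.0), (6, 4, 0.9),
    ])
    added_harmonics: list = field(default_factory=lambda: [
        (10, 5, 1.0), (12, -7, 0.9), (14, 9, 0.8),
    ])
    patches: list = field(default_factory=lambda: [
        (np.array([0.80, 0.48, 0.36]) / np.linalg.norm([0.80, 0.48, 0.36]), 0.65),
        (np.array([-0.45, 0.76, -0.47]) / np.linalg.norm([-0.45, 0.76, -0.47]), 0.65),
    ])
    axes: tuple = (1.15, 1.0, 0.85)  # triaxial stretch of the base shape
    subject_sd: float = 0.15       # mm, between-subject amplitude jitter
    vertex_noise_sd: float = 0.05  # mm, isotropic per-vertex noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius_early <= 0 or self.base_radius_late <= 0:
            raise ValueError("radii must be positive")
        for _, _, amp in list(self.base_harmonics) + list(self.added_harmonics):
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
        for _, ang in self.patches:
            if not (0 < ang < np.pi):
                raise ValueError("patch angular radii must be in (0, pi)")


def real_sph_harm(degree: int, order: int, directions: np.ndarray) -> np.ndarray:
    """Real spherical harmonic Y_lm evaluated at unit direction vectors."""
    d = np.asarray(directions)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(d[:, 1], d[:, 0])               # azimuth
    y = sph_harm_y(degree, abs(order), theta, phi)
    if order > 0:
        return np.sqrt(2.0) * (-1.0) ** order * y.real
    if order < 0:
        return np.sqrt(2.0) * (-1.0) ** order * y.imag
    return y.real


def icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosphere fixture: 10 * 4^s + 2 vertices, 20 * 4^s triangles."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                        region_label=f"icosphere{subdivisions}")


def _patch_weights(directions: np.ndarray, patches, taper_frac: float = 0.2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth membership weight in [0, 1] and integer patch label (-1 outside).

    Full weight inside (1 - taper_frac) of the cap radius, cosine falloff
    to zero at the rim."""
    n = len(directions)
    weights = np.zeros(n)
    labels = -np.ones(n, dtype=np.int64)
    for p_idx, (center, ang_radius) in enumerate(patches):
        center = np.asarray(center, dtype=np.float64)
        center = center / np.linalg.norm(center)
        theta = np.arccos(np.clip(directions @ center, -1.0, 1.0))
        inner = (1.0 - taper_frac) * ang_radius
        w = np.zeros(n)
        w[theta <= inner] = 1.0
        rim = (theta > inner) & (theta < ang_radius)
        w[rim] = 0.5 * (1.0 + np.cos(
            np.pi * (theta[rim] - inner) / (ang_radius - inner)))
        weights = np.maximum(weights, w)
        labels[theta <= ang_radius] = p_idx
    return weights, labels


def _fold_field(directions: np.ndarray, harmonics) -> np.ndarray:
    out = np.zeros(len(directions))
    for degree, order, amp in harmonics:
        if amp > 0:
            out += amp * real_sph_harm(degree, order, directions)
    return out


def generate_longitudinal_pair(
    spec: FoldingSpec, subdivision: int = 3
) -> tuple[TriangleMesh, TriangleMesh, Correspondence, np.ndarray]:
    """One subject's early and late surfaces with ground truth.

    Returns ``(mesh_early, mesh_late, ground_truth_corr, patch_labels)``.
    Both meshes are built on the same icosphere directions, so the ground
    truth correspondence is the identity.  The late surface is the early
    base geometry under a uniform radial growth scale, plus the late-only
    harmonics confined to the patches.
    """
    rng = np.random.default_rng(spec.seed)
    base = icosphere(subdivision)
    directions = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    f_base = _fold_field(directions, spec.base_harmonics)
    f_added = _fold_field(directions, spec.added_harmonics)
    weights, labels = _patch_weights(directions, spec.patches)
    growth = spec.base_radius_late / spec.base_radius_early

    r_early = spec.base_radius_early + f_base
    r_late = growth * (spec.base_radius_early + f_base) + f_added * weights
    for name, r, radius in (("early", r_early, spec.base_radius_early),
                            ("late", r_late, spec.base_radius_late)):
        disp = np.abs(r - radius)
        if np.any(disp > 0.8 * radius):
            raise ValueError(
                f"{name} surface: displacement exceeds 0.8 x radius "
                "(self-intersection risk); reduce amplitudes"
            )
    noise_e = rng.normal(0.0, spec.vertex_noise_sd, size=(len(directions), 3)) \
        if spec.vertex_noise_sd > 0 else 0.0
    noise_l = rng.normal(0.0, spec.vertex_noise_sd, size=(len(directions), 3)) \
        if spec.vertex_noise_sd > 0 else 0.0
    # triaxial stretch: brains are ellipsoidal, not spherical, which also
    # makes the global orientation identifiable for registration
    axes = np.asarray(spec.axes, dtype=np.float64)
    mesh_early = TriangleMesh(r_early[:, None] * directions * axes + noise_e,
                              base.triangles.copy(), "early")
    mesh_late = TriangleMesh(r_late[:, None] * directions * axes + noise_l,
                             base.triangles.copy(), "late")
    corr = Correspondence(np.arange(len(directions)),
                          np.zeros(len(directions)), "early", "late")
    return mesh_early, mesh_late, corr, labels


def _radius_for_area(area_mm2: float) -> float:
    return float(np.sqrt(area_mm2 / (4.0 * np.pi)))


def generate_cohort(
    spec: FoldingSpec,
    n_subjects: int = 9,
    age_schedule: list[tuple[float, float]] | None = None,
    seed: int = 0,
    subdivision: int = 3,
    area_slope_cm2_per_week: float = 8.8,
    area_ref_cm2: float = 113.1,
    ega_ref: float = 31.6,
):
    """A cohort of longitudinal pairs with linear area growth in EGA.

    Per-subject radii are set so that the (near-spherical) surface area
    follows ``area_ref + slope * (ega - ega_ref)`` in cm^2, and harmonic
    amplitudes receive seeded between-subject jitter of sd ``subject_sd``.
    Returns ``(pairs, records)`` where ``pairs`` is a list of
    (mesh_early, mesh_late, corr, patch_labels) and ``records`` the
    matching ``SubjectRecord`` metadata.

    Defaults emulate the study design: nine subjects, scans near 31.6 and
    41.7 weeks EGA, area slope of order 10 cm^2/week.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if age_schedule is None:
        age_schedule = DEFAULT_AGE_SCHEDULE
    if len(age_schedule) < n_subjects:
        raise ValueError("age_schedule shorter than n_subjects")
    rng = np.random.default_rng(seed)
    pairs = []
    records = []
    for s_idx in range(n_subjects):
        ega1, ega2 = age_schedule[s_idx]
        area1 = (area_ref_cm2 + area_slope_cm2_per_week * (ega1 - ega_ref)) * 100.0
        area2 = (area_ref_cm2 + area_slope_cm2_per_week * (ega2 - ega_ref)) * 100.0
        if area1 <= 0 or area2 <= 0:
            raise ValueError("area schedule gives non-positive area")
        jitter = rng.normal(0.0, spec.subject_sd,
                            size=len(spec.base_harmonics) + len(spec.added_harmonics))
        base_h = [(l, m, max(a + jitter[j], 0.0))
                  for j, (l, m, a) in enumerate(spec.base_harmonics)]
        added_h = [(l, m, max(a + jitter[len(spec.base_harmonics) + j], 0.0))
                   for j, (l, m, a) in enumerate(spec.added_harmonics)]
        sub_spec = replace(
            spec,
            base_radius_early=_radius_for_area(area1),
            base_radius_late=_radius_for_area(area2),
            base_harmonics=base_h,
            added_harmonics=added_h,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        pair = generate_longitudinal_pair(sub_spec, subdivision)
        # folding and the ellipsoidal stretch change the area slightly;
        # rescale each mesh uniformly so the target area is met exactly
        from .mesh import surface_area
        early, late, corr, labels = pair
        early.vertices *= np.sqrt(area1 / surface_area(early))
        late.vertices *= np.sqrt(area2 / surface_area(late))
        pairs.append((early, late, corr, labels))
        if s_idx < len(STUDY_COHORT_TABLE):
            sid, gab = STUDY_COHORT_TABLE[s_idx][0], _pwd(STUDY_COHORT_TABLE[s_idx][1])
        else:
            sid, gab = f"s{s_idx:02d}", ega1 - 5.0
        records.append(SubjectRecord(
            subject_id=f"sim_{sid}",
            ga_birth=gab,
            ega_scan1=float(ega1),
            ega_scan2=float(ega2),
            qc_scan1="synthetic",
            qc_scan2="synthetic",
        ))
    return pairs, records


def _cylinder(radius: float = 5.0, height: float = 20.0,
              sections: int = 48, rings: int = 17) -> TriangleMesh:
    """Closed cylinder with height-subdivided tube (flat caps with apex
    vertices), so the tube has a proper interior for curvature tests."""
    phis = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    zs = np.linspace(-height / 2, height / 2, rings)
    ring_pts = np.array([[radius * np.cos(p), radius * np.sin(p), z]
                         for z in zs for p in phis])
    bottom_apex = np.array([[0.0, 0.0, -height / 2]])
    top_apex = np.array([[0.0, 0.0, height / 2]])
    verts = np.vstack([ring_pts, bottom_apex, top_apex])
    i_bottom = len(ring_pts)
    i_top = i_bottom + 1
    tris = []
    for r in range(rings - 1):
        for s in range(sections):
            a = r * sections + s
            b = r * sections + (s + 1) % sections
            c = a + sections
            d = b + sections
            tris.append((a, b, d))
            tris.append((a, d, c))
    for s in range(sections):  # caps, outward-oriented
        a, b = s, (s + 1) % sections
        tris.append((b, a, i_bottom))
        top0 = (rings - 1) * sections
        tris.append((top0 + a, top0 + b, i_top))
    return TriangleMesh(verts, np.array(tris), "cylinder")


def _saddle(extent: float = 1.0, n: int = 15) -> TriangleMesh:
    """Open saddle patch z = x^2 - y^2 on a regular grid (G < 0 everywhere)."""
    xs = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(xs, xs)
    zz = xx ** 2 - yy ** 2
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris.append((a, a + 1, a + n))
            tris.append((a + 1, a + n + 1, a + n))
    return TriangleMesh(verts, np.array(tris), "saddle")


def _tetrahedron() -> TriangleMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    tris = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, tris, "tetrahedron")


def _cube() -> TriangleMesh:
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "cube")


def _two_components() -> TriangleMesh:
    a = icosphere(3, radius=10.0)          # 642 vertices
    b = icosphere(2, radius=4.0)           # 162 vertices
    verts = np.vstack([a.vertices, b.vertices + np.array([40.0, 0.0, 0.0])])
    tris = np.vstack([a.triangles, b.triangles + a.n_vertices])
    return TriangleMesh(verts, tris, "two-components")


def fixture_suite() -> dict[str, TriangleMesh]:
    """Deterministic analytic fixtures shared across the test-suite."""
    return {
        "icosphere2": icosphere(2, radius=10.0),
        "icosphere3": icosphere(3, radius=10.0),
        "icosphere4": icosphere(4, radius=10.0),
        "cylinder": _cylinder(),
        "saddle": _saddle(),
        "two_components": _two_components(),
        "tetrahedron": _tetrahedron(),
        "cube": _cube(),
    }
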