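"""Joint-Spectral Matching (JSM) of two cortical surfaces.

The two meshes become the layers of a dual-layered graph, connected by a
sparse set of correspondence links taken from an initial (CPD-seeded)
spatial alignment.  The joint Laplacian of this graph yields *shared*
eigenmodes: both surfaces receive coordinates in one common spectral space,
where a plain nearest-neighbor search defines the final point-wise
correspondence.  Matching works despite large differences in size and
folding because near-isometric surfaces have nearly identical low-frequency
spectral representations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import KDTree

from .cpd import Correspondence, RigidTransform, cpd_rigid, \
    nearest_neighbor_correspondence, subsample_for_cpd
from .mesh import TriangleMesh
from .spectral import SpectralEmbedding, WeightedGraph, build_graph, \
    spectral_embedding

__all__ = [
    "JointGraph",
    "MismatchMap",
    "MatchConfig",
    "build_joint_graph",
    "joint_spectral_match",
    "match_pipeline",
    "matching_consistency",
]

log = logging.getLogger(__name__)


@dataclass
class MatchConfig:
    """Tunable parameters of the CPD + JSM matching chain."""

    k: int = 5                       # spectral components
    link_fraction: float = 0.2       # fraction of init links kept
    link_weight_factor: float = 1.0  # x mean intra-layer edge weight
    cpd_subsample: int = 3000        # points for the CPD stage
    cpd_outlier_weight: float = 0.1
    cpd_use_scale: bool = True
    cpd_max_iter: int = 120
    cpd_tol: float = 1e-6
    cpd_starts: int = 5              # identity + 4 principal-axes starts
    seed: int = 0


@dataclass
class JointGraph:
    """Dual-layered graph: two mesh layers plus inter-layer links."""

    layer_a: WeightedGraph
    layer_b: WeightedGraph
    links: np.ndarray        # (L, 2) [vertex_a, vertex_b]
    link_weight: float

    @property
    def n_a(self) -> int:
        return self.layer_a.node_count

    @property
    def n_b(self) -> int:
        return self.layer_b.node_count

    def combined(self) -> WeightedGraph:
        """The (n_a + n_b)-node weighted graph of both layers and links."""
        n_a, n_b = self.n_a, self.n_b
        w = sp.block_diag([self.layer_a.weights, self.layer_b.weights]).tolil()
        ia = self.links[:, 0]
        ib = self.links[:, 1] + n_a
        w[ia, ib] = self.link_weight
        w[ib, ia] = self.link_weight
        w = w.tocsr()
        degrees = np.asarray(w.sum(axis=1)).ravel()
        return WeightedGraph(w, degrees)


@dataclass
class MismatchMap:
    """Per-vertex Euclidean disagreement (mm) between two candidate
    correspondences; exactly -1 flags vertices absent from one mesh."""

    values: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        valid = self.values >= 0
        sentinel = self.values == -1.0
        assert np.all(valid | sentinel)


def build_joint_graph(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    init_corr: Correspondence,
    link_fraction: float = 0.2,
    link_weight_factor: float = 1.0,
    seed: int = 0,
) -> JointGraph:
    """Connect the two mesh layers with a seeded subset of init-corr links.

    Links are placed on a uniform random subset (``link_fraction``) of the
    initial correspondence pairs; each link weight is ``link_weight_factor``
    times the mean intra-layer edge weight.  Sparse links preserve each
    layer's intrinsic geometry while still coupling the eigenmodes.
    """
    if not (0 < link_fraction <= 1):
        raise ValueError("link_fraction must be in (0, 1]")
    if len(init_corr) != mesh_a.n_vertices:
        raise ValueError("init_corr must map every vertex of mesh_a")
    layer_a = build_graph(mesh_a)
    layer_b = build_graph(mesh_b)
    n_links = int(np.ceil(link_fraction * len(init_corr)))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(init_corr), size=n_links, replace=False))
    links = np.column_stack([chosen, init_corr.map[chosen]])
    if len(links) == 0:
        raise ValueError("no correspondence links: layers would be disconnected")
    mean_w = (layer_a.weights.sum() + layer_b.weights.sum()) / (
        layer_a.weights.nnz + layer_b.weights.nnz
    )
    joint = JointGraph(layer_a, layer_b, links, link_weight_factor * mean_w)
    # connectivity of the combined graph is checked by the eigensolver
    # (lambda_1 ~ 0); a cheap structural check here catches the no-link case
    return joint


def joint_spectral_match(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    init_corr: Correspondence,
    k: int = 5,
    link_fraction: float = 0.2,
    link_weight_factor: float = 1.0,
    seed: int = 0,
) -> tuple[Correspondence, Correspondence, SpectralEmbedding]:
    """Shared-eigenmode embedding and nearest-neighbor correspondences.

    Returns ``(corr_a_to_b, corr_b_to_a, shared_embedding)``.  The shared
    embedding covers all ``n_a + n_b`` nodes (layer a first).
    """
    joint = build_joint_graph(mesh_a, mesh_b, init_corr,
                              link_fraction, link_weight_factor, seed)
    emb = spectral_embedding(joint.combined(), k)
    coords_a = emb.modes[: joint.n_a]
    coords_b = emb.modes[joint.n_a:]
    tree_b = KDTree(coords_b)
    dist_ab, idx_ab = tree_b.query(coords_a, k=1)
    tree_a = KDTree(coords_a)
    dist_ba, idx_ba = tree_a.query(coords_b, k=1)
    corr_ab = Correspondence(idx_ab[:, 0], dist_ab[:, 0],
                             mesh_a.region_label or "a", mesh_b.region_label or "b")
    corr_ba = Correspondence(idx_ba[:, 0], dist_ba[:, 0],
                             mesh_b.region_label or "b", mesh_a.region_label or "a")
    return corr_ab, corr_ba, emb


def match_pipeline(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    config: MatchConfig | None = None,
) -> Correspondence:
    """Full correspondence chain: CPD init -> spatial NN -> JSM.

    Stages: (1) seeded uniform subsampling of both meshes, (2) similarity
    CPD aligning mesh_a onto mesh_b, (3) exact nearest-neighbor map of the
    transformed full mesh_a onto mesh_b as the initial correspondence,
    (4) joint spectral matching.  Returns the a→b correspondence (for each
    mesh_a vertex its nearest mesh_b vertex in the shared spectral space).
    """
    config = config or MatchConfig()
    for name, mesh in (("mesh_a", mesh_a), ("mesh_b", mesh_b)):
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(mesh.vertex_adjacency(), directed=False)
        if n_comp != 1:
            raise ValueError(
                f"{name} has {n_comp} connected components; "
                "extract the largest component first (mesh.largest_component)"
            )
    log.info("stage subsample: n=%d", config.cpd_subsample)
    pts_a, _ = subsample_for_cpd(mesh_a, config.cpd_subsample, config.seed)
    pts_b, _ = subsample_for_cpd(mesh_b, config.cpd_subsample, config.seed + 1)
    log.info("stage cpd: %d -> %d points", len(pts_a), len(pts_b))
    transform, _ = cpd_rigid(
        pts_a, pts_b,
        outlier_weight=config.cpd_outlier_weight,
        max_iter=config.cpd_max_iter,
        tol=config.cpd_tol,
        use_scale=config.cpd_use_scale,
        seed=config.seed,
        n_starts=config.cpd_starts,
    )
    log.info("stage init: nearest-neighbor map after CPD (scale %.3f)",
             transform.scale)
    init = nearest_neighbor_correspondence(transform.apply(mesh_a.vertices),
                                           mesh_b.vertices)
    log.info("stage jsm: k=%d link_fraction=%.2f", config.k, config.link_fraction)
    corr_ab, _, _ = joint_spectral_match(
        mesh_a, mesh_b, init,
        k=config.k,
        link_fraction=config.link_fraction,
        link_weight_factor=config.link_weight_factor,
        seed=config.seed,
    )
    return corr_ab


def matching_consistency(
    corr_regional: Correspondence,
    corr_whole: Correspondence,
    region_to_whole_a: np.ndarray,
    region_to_whole_b: np.ndarray,
    mesh_b_whole: TriangleMesh,
) -> MismatchMap:
    """Disagreement between a regional and a whole-surface correspondence.

    For each scan-1 vertex of the whole mesh that also exists in the
    regional mesh, the mismatch is the Euclidean distance (mm) between the
    scan-2 point selected by the regional match and the one selected by the
    whole-surface match.  Scan-1 vertices absent from the regional mesh get
    the sentinel -1 and are excluded from the mean/sd summary.
    """
    region_to_whole_a = np.asarray(region_to_whole_a, dtype=np.int64)
    region_to_whole_b = np.asarray(region_to_whole_b, dtype=np.int64)
    if len(region_to_whole_a) != len(corr_regional):
        raise ValueError("region_to_whole_a length must match corr_regional")
    if corr_regional.map.max() >= len(region_to_whole_b):
        raise ValueError("corr_regional targets exceed region_to_whole_b")
    n_whole_a = len(corr_whole)
    if region_to_whole_a.max() >= n_whole_a:
        raise ValueError("region_to_whole_a indices exceed whole mesh a")
    values = np.full(n_whole_a, -1.0)
    whole_targets = corr_whole.map[region_to_whole_a]
    regional_targets = region_to_whole_b[corr_regional.map]
    d = np.linalg.norm(
        mesh_b_whole.vertices[whole_targets]
        - mesh_b_whole.vertices[regional_targets],
        axis=1,
    )
    values[region_to_whole_a] = d
    return MismatchMap(values, float(d.mean()), float(d.std(ddof=1)))
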