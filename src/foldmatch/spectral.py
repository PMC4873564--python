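"""Graph-Laplacian spectral embedding of triangle meshes.

A surface mesh is treated as a weighted graph whose edge weights are the
reciprocal edge lengths, w_ij = 1/||x_i - x_j|| for mesh edges and zero
otherwise.  The random-walk (general) Laplacian L = D^{-1}(D - W) is
diagonalized and the k smallest non-null eigenmodes give every vertex k
spectral coordinates.  Near-isometric surfaces — the same cortex at two
ages, folded to different degrees — have very similar embeddings, which is
what makes correspondence search tractable in this space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import linear_sum_assignment

from .mesh import TriangleMesh

__all__ = [
    "WeightedGraph",
    "SpectralEmbedding",
    "build_graph",
    "general_laplacian",
    "spectral_embedding",
    "align_modes",
]

# Eigenvalues of sparse solves can drift a hair below 0 or above the
# random-walk bound of 2; clip within this tolerance only.
_EIG_TOL = 1e-9


@dataclass
class WeightedGraph:
    """Inverse-distance weighted adjacency of a mesh (or joint graph)."""

    weights: sp.csr_matrix  # symmetric, zero diagonal, 1/mm
    degrees: np.ndarray     # d_ii = sum_j w_ij

    @property
    def node_count(self) -> int:
        return self.weights.shape[0]


@dataclass
class SpectralEmbedding:
    """Truncated spectral coordinates of every graph node.

    ``eigenvalues`` are the k smallest non-null eigenvalues of the general
    Laplacian, ascending.  ``modes`` is (n_nodes, k); column j is the
    eigenvector u_j, D-orthonormal, deterministically signed, and (by
    default) scaled by lambda_j^{-1/2} so that coarse modes dominate
    nearest-neighbor distances.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    k: int
    lambda_weighted: bool = True

    def __post_init__(self) -> None:
        assert self.modes.shape[1] == self.k == len(self.eigenvalues)


def build_graph(mesh: TriangleMesh) -> WeightedGraph:
    """Weighted adjacency with w_ij = 1/edge length on mesh edges."""
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    if np.any(lengths <= 0):
        raise ValueError("coincident edge endpoints give infinite weight")
    w = 1.0 / lengths
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    weights = sp.coo_matrix((np.concatenate([w, w]), (rows, cols)),
                            shape=(n, n)).tocsr()
    degrees = np.asarray(weights.sum(axis=1)).ravel()
    if np.any(degrees <= 0):
        raise ValueError("graph has isolated nodes (zero degree)")
    return WeightedGraph(weights, degrees)


def general_laplacian(graph: WeightedGraph) -> sp.csr_matrix:
    """The random-walk Laplacian L = D^{-1}(D - W), rows summing to zero."""
    if np.any(graph.degrees <= 0):
        raise ValueError("zero-degree node")
    inv_d = sp.diags(1.0 / graph.degrees)
    d = sp.diags(graph.degrees)
    return (inv_d @ (d - graph.weights)).tocsr()


def _sorted_eigpairs(graph: WeightedGraph, n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Smallest eigenpairs of (D - W) u = lambda D u, ascending.

    L is non-symmetric; the equivalent symmetric normalized problem
    N y = lambda y with N = I - D^{-1/2} W D^{-1/2} and y = D^{1/2} u has
    the same spectrum and stable solvers.  Dense path for small graphs,
    shift-invert Lanczos otherwise.
    """
    n = graph.node_count
    d_isqrt = 1.0 / np.sqrt(graph.degrees)
    if n <= 1200:
        w_norm = (graph.weights.multiply(d_isqrt[:, None])).multiply(d_isqrt[None, :])
        n_mat = np.eye(n) - w_norm.toarray()
        vals, vecs = scipy.linalg.eigh(n_mat)
        vals, vecs = vals[:n_pairs], vecs[:, :n_pairs]
    else:
        w_norm = (graph.weights.multiply(d_isqrt[:, None])).multiply(d_isqrt[None, :])
        n_mat = (sp.eye(n) - w_norm).tocsc()
        # N is PSD; a small negative shift keeps the factorization definite.
        vals, vecs = spla.eigsh(n_mat, k=n_pairs, sigma=-0.05, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    # back-transform: u = D^{-1/2} y; then u^T D u = y^T y = 1 already
    u = d_isqrt[:, None] * vecs
    return np.clip(vals, 0.0, None), u


def spectral_embedding(graph: WeightedGraph, k: int = 5, *,
                       lambda_weighted: bool = True) -> SpectralEmbedding:
    """k-dimensional spectral embedding from the smallest non-null modes.

    The null mode u_0 (constant eigenvector, lambda_0 = 0) is discarded.
    Raises if the graph is disconnected (lambda_1 ~ 0), advising component
    extraction first.
    """
    n = graph.node_count
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    vals, u = _sorted_eigpairs(graph, k + 1)
    if vals[1] <= 1e-10:  # spectrum of L lives in [0, 2]
        raise ValueError(
            "second eigenvalue is ~0: graph is disconnected; "
            "extract the largest component first (mesh.largest_component)"
        )
    if vals[0] > 1e-8 * vals[1]:
        raise RuntimeError("first eigenvalue is not numerically zero")
    vals, u = vals[1:], u[:, 1:]
    # deterministic sign: largest-magnitude entry positive
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    u = u * signs[None, :]
    if lambda_weighted:
        u = u / np.sqrt(vals)[None, :]
    return SpectralEmbedding(vals, u, k, lambda_weighted)


def _degenerate_groups(eigenvalues: np.ndarray, rel_gap: float = 0.05) -> list[list[int]]:
    """Partition mode indices into runs of near-degenerate eigenvalues."""
    groups: list[list[int]] = [[0]]
    for j in range(1, len(eigenvalues)):
        lam0, lam1 = eigenvalues[j - 1], eigenvalues[j]
        if (lam1 - lam0) / max(lam1, 1e-300) < rel_gap:
            groups[-1].append(j)
        else:
            groups.append([j])
    return groups


def align_modes(emb_a: SpectralEmbedding, emb_b: SpectralEmbedding,
                corr_a_to_b: np.ndarray, rel_gap: float = 0.05) -> SpectralEmbedding:
    """Resolve sign flips and orderings of ``emb_b`` against ``emb_a``.

    Eigenmodes are defined only up to sign, and up to permutation within
    (near-)degenerate eigenvalue groups.  Given a vertex correspondence
    a→b, modes of b are permuted within near-degenerate groups (relative
    gap < ``rel_gap``) and sign-flipped to maximize correlation with a's
    modes, which makes mode-by-mode comparison and visualization sensible.
    """
    corr_a_to_b = np.asarray(corr_a_to_b, dtype=np.int64)
    a = emb_a.modes
    b_thru = emb_b.modes[corr_a_to_b]  # (n_a, k)
    a_c = a - a.mean(0)
    b_c = b_thru - b_thru.mean(0)
    denom = np.outer(np.linalg.norm(a_c, axis=0), np.linalg.norm(b_c, axis=0))
    corr_mat = (a_c.T @ b_c) / np.maximum(denom, 1e-300)

    k = emb_b.k
    perm = np.arange(k)
    signs = np.ones(k)
    for group in _degenerate_groups(emb_b.eigenvalues, rel_gap):
        if len(group) == 1:
            j = group[0]
            signs[j] = 1.0 if corr_mat[j, j] >= 0 else -1.0
            continue
        sub = np.abs(corr_mat[np.ix_(group, group)])
        rows, cols = linear_sum_assignment(-sub)
        for r, c in zip(rows, cols):
            perm[group[r]] = group[c]
            signs[group[r]] = 1.0 if corr_mat[group[r], group[c]] >= 0 else -1.0
    modes = emb_b.modes[:, perm] * signs[None, :]
    return SpectralEmbedding(emb_b.eigenvalues[perm], modes, k, emb_b.lambda_weighted)
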