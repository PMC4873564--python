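"""Rigid / similarity Coherent Point Drift for initial surface alignment.

CPD treats the source point cloud as the centroids of an isotropic Gaussian
mixture fitted to the target cloud by EM, with a uniform component that
absorbs outliers.  Only a rigid (optionally scaled) transform of the source
is optimized, which is enough to seed the spectral matching: the two scans
of one infant differ greatly in size and folding, so a similarity transform
is estimated by default (strict-rigid behavior via ``use_scale=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.neighbors import KDTree

from .mesh import TriangleMesh

__all__ = [
    "RigidTransform",
    "Correspondence",
    "cpd_rigid",
    "subsample_for_cpd",
    "nearest_neighbor_correspondence",
]


@dataclass
class RigidTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray            # (3, 3), det = +1
    translation: np.ndarray         # (3,), mm
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must have determinant +1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(r_inv, -r_inv @ self.translation / self.scale,
                              1.0 / self.scale)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (scale folded into the linear part)."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    def save(self, path) -> None:
        np.savetxt(path, np.vstack([self.as_matrix(), [self.scale, 0, 0, 0]]),
                   header="rows 0-3: homogeneous transform; row 4: scale")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)


@dataclass
class Correspondence:
    """A per-source-vertex map onto target vertices.

    ``map[i]`` is the target index matched to source vertex i (not
    necessarily injective); ``distances[i]`` is the distance of the match
    in whatever space the match was made (spatial mm or spectral units).
    """

    map: np.ndarray
    distances: np.ndarray | None = None
    source_mesh_id: str = ""
    target_mesh_id: str = ""

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.map)

    def save(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([np.arange(len(self.map)), self.map]),
            fmt="%d",
            header=f"source={self.source_mesh_id} target={self.target_mesh_id}\n"
                   "source_index target_index",
        )

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        return cls(np.arange(n), np.zeros(n))


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    if len(points) < 4:
        raise ValueError(f"{name}: need at least 4 points")
    centered = points - points.mean(0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] < 1e-9 * max(s[0], 1e-300):
        raise ValueError(f"{name}: points are coplanar/collinear (degenerate)")


def cpd_rigid(
    source_points: np.ndarray,
    target_points: np.ndarray,
    outlier_weight: float = 0.1,
    max_iter: int = 120,
    tol: float = 1e-6,
    use_scale: bool = True,
    seed: int | None = None,
    n_starts: int = 1,
) -> tuple[RigidTransform, Correspondence]:
    """EM point-set registration of ``source`` onto ``target``.

    Returns the transform that maps source points onto the target cloud and
    the maximum-posterior hard assignment of each source point to a target
    point.  Convergence: relative change of the negative log-likelihood
    < ``tol``, else ``max_iter`` with a warning.

    EM converges to a local optimum; for shapes with weak orientation cues
    ``n_starts > 1`` restarts from additional seeded random initial
    rotations and keeps the run with the best final objective.  With the
    default single start the algorithm is deterministic and ``seed`` is
    unused.
    """
    x = np.asarray(target_points, dtype=np.float64)
    y = np.asarray(source_points, dtype=np.float64)
    _check_nondegenerate(x, "target")
    _check_nondegenerate(y, "source")
    if not (0 <= outlier_weight < 1):
        raise ValueError("outlier_weight must be in [0, 1)")
    starts = [np.eye(3)]
    if n_starts > 1:
        # principal-axes candidates: align the clouds' PCA frames, trying
        # the four proper sign combinations; EM refines from each
        starts += _pca_starts(x, y)[: n_starts - 1]
    if n_starts > 5:
        rng = np.random.default_rng(seed or 0)
        from scipy.spatial.transform import Rotation
        starts += [
            Rotation.random(rng=rng).as_matrix() for _ in range(n_starts - 5)
        ]
    best = None
    for r0 in starts:
        result = _cpd_rigid_single(x, y, r0, outlier_weight, max_iter, tol,
                                   use_scale, warn=(len(starts) == 1))
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    transform, p_mat, objective = best
    # hard assignment: for each source centroid, the max-posterior target
    # point; ties broken by lowest target index (argmax behavior).
    hard = np.argmax(p_mat, axis=1)
    ty = transform.apply(y)
    dists = np.linalg.norm(ty - x[hard], axis=1)
    corr = Correspondence(hard, dists)
    corr.objective_trace = objective  # type: ignore[attr-defined]
    return transform, corr


def _pca_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    def frame(p: np.ndarray) -> np.ndarray:
        c = p - p.mean(0)
        _, vecs = np.linalg.eigh(c.T @ c)
        return vecs[:, ::-1]  # descending variance

    vx, vy = frame(x), frame(y)
    starts = []
    for sx in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r0 = vx @ np.diag(np.asarray(sx, dtype=np.float64)) @ vy.T
        if np.linalg.det(r0) < 0:  # eigh may return either handedness
            r0 = vx @ np.diag(np.asarray(sx) * np.array([1, 1, -1.0])) @ vy.T
        starts.append(r0)
    return starts


def _cpd_rigid_single(
    x: np.ndarray,
    y: np.ndarray,
    r0: np.ndarray,
    outlier_weight: float,
    max_iter: int,
    tol: float,
    use_scale: bool,
    warn: bool = True,
) -> tuple[RigidTransform, np.ndarray, list[float]]:
    n, m, d = len(x), len(y), 3
    r = r0.copy()
    t = x.mean(0) - r @ y.mean(0)
    s = 1.0
    # standard CPD initialization of sigma^2: mean squared pairwise distance
    sigma2 = (
        (x ** 2).sum() * m + (y ** 2).sum() * n
        - 2.0 * x.sum(0) @ y.sum(0)
    ) / (d * n * m)
    # fixed uniform-outlier density over the target bounding box
    extent = np.maximum(x.max(0) - x.min(0), 1e-12)
    uniform_density = 1.0 / np.prod(extent)
    # a perfect fit sends sigma^2 -> 0; stop there (clamping any further
    # would break the EM monotonicity guarantee)
    sigma2_floor = 1e-8 * float((extent ** 2).mean())

    objective = []  # negative log-likelihood per iteration
    p_mat = np.zeros((m, n))
    from scipy.spatial.distance import cdist

    for iteration in range(max_iter):
        ty = s * y @ r.T + t
        gauss = cdist(ty, x, "sqeuclidean")
        gauss *= -1.0 / (2.0 * sigma2)
        np.exp(gauss, out=gauss)
        gauss /= (2.0 * np.pi * sigma2) ** (d / 2)
        mixture = (1.0 - outlier_weight) * gauss.sum(0) / m \
            + outlier_weight * uniform_density
        mixture = np.maximum(mixture, 1e-300)
        nll = -np.log(mixture).sum()
        objective.append(nll)
        p_mat = (1.0 - outlier_weight) / m * gauss / mixture[None, :]

        n_p = p_mat.sum()
        if n_p < 1e-12:
            warnings.warn("all mass assigned to the outlier component")
            break
        p1 = p_mat.sum(1)        # (m,)
        pt1 = p_mat.sum(0)       # (n,)
        mu_x = (pt1 @ x) / n_p
        mu_y = (p1 @ y) / n_p
        xc = x - mu_x
        yc = y - mu_y
        a = xc.T @ (p_mat.T @ yc)      # (d, d)
        u_svd, _, vt_svd = np.linalg.svd(a)
        c = np.eye(d)
        c[-1, -1] = np.linalg.det(u_svd @ vt_svd)
        r = u_svd @ c @ vt_svd
        trace_ar = np.trace(a.T @ r)
        ypy = (p1 @ (yc ** 2).sum(1))
        if use_scale:
            s = trace_ar / ypy
        else:
            s = 1.0
        t = mu_x - s * r @ mu_y
        xpx = (pt1 @ (xc ** 2).sum(1))
        sigma2_new = (xpx - s * trace_ar) / (n_p * d)
        if sigma2_new <= sigma2_floor:
            sigma2 = sigma2_floor
            break
        sigma2_prev, sigma2 = sigma2, sigma2_new

        # converged when the transform's action on the source stabilizes
        # (the NLL alone keeps annealing sigma^2 for a long tail); a minimum
        # iteration count lets sigma^2 contract to the data-fit scale first
        ty_new = s * y @ r.T + t
        move = float(np.abs(ty_new - ty).mean())
        if iteration >= 10 and move < 1e-5 * float(extent.mean()):
            break
        if iteration > 0:
            rel = abs(objective[-2] - objective[-1]) / max(abs(objective[-2]), 1e-300)
            if rel < tol:
                break
    else:
        if warn:
            warnings.warn(
                f"CPD did not converge in {max_iter} iterations "
                f"(last relative change {rel:.2e})"
            )

    return RigidTransform(r, t, s), p_mat, objective


def subsample_for_cpd(
    mesh: TriangleMesh, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform vertex subsample for the O(NM) CPD stage.

    Returns ``(points, indices)`` where ``indices`` maps subsample rows back
    to full-mesh vertex indices.  With ``n >= n_vertices`` the identity
    subsample is returned.
    """
    n_vert = mesh.n_vertices
    if n >= n_vert:
        return mesh.vertices.copy(), np.arange(n_vert)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_vert, size=n, replace=False))
    return mesh.vertices[idx], idx


def nearest_neighbor_correspondence(
    source_points: np.ndarray, target_points: np.ndarray
) -> Correspondence:
    """Exact nearest-neighbor map source -> target (KD-tree, lowest-index ties)."""
    tree = KDTree(np.asarray(target_points))
    dist, idx = tree.query(np.asarray(source_points), k=1)
    return Correspondence(idx[:, 0], dist[:, 0])
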