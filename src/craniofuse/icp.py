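"""Point-to-point and point-to-plane ICP with correspondence-threshold gating.

Correspondences run source→target: every source point takes its single
nearest target neighbour (KD-tree accelerated) and the pair is kept iff the
distance is strictly below the threshold. Estimation minimizes either the
point-to-point objective Σ‖p − Tq‖² (closed-form SVD solution) or the
point-to-plane objective Σ((p − Tq)·n_p)² (small-angle linearization to a
6×6 system, re-orthonormalized through the rotation-vector exponential).

The loop stops when the relative change of the per-correspondence mean
objective drops below ``rel_change_tol`` (default 1e-6) or after
``max_iterations`` (default 30); the returned transform is the composition of
the initial transform and every per-iteration increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometryError, InvalidInputError
from .geometry import PointCloud, RigidTransform

__all__ = [
    "CorrespondenceSet",
    "ICPConfig",
    "ICPResult",
    "find_correspondences",
    "estimate_normals",
    "solve_point_to_point",
    "solve_point_to_plane",
    "run_icp",
]


@dataclass
class CorrespondenceSet:
    """Matched pairs K = {(p, q)}: target index p, source index q, distance mm."""

    target_indices: np.ndarray
    source_indices: np.ndarray
    distances: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.target_indices = np.asarray(self.target_indices, dtype=np.int64)
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if not (self.target_indices.shape == self.source_indices.shape == self.distances.shape):
            raise InvalidInputError("correspondence arrays must share a shape")

    def __len__(self) -> int:
        return self.target_indices.shape[0]

    @property
    def pairs(self) -> list[tuple[int, int, float]]:
        return list(zip(self.target_indices.tolist(), self.source_indices.tolist(), self.distances.tolist()))


@dataclass(frozen=True)
class ICPConfig:
    threshold: float
    max_iterations: int = 30
    rel_change_tol: float = 1e-6
    variant: Literal["point-to-point", "point-to-plane"] = "point-to-plane"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise InvalidInputError("correspondence threshold must be positive")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be at least 1")


@dataclass
class ICPResult:
    transform: RigidTransform
    objective_trace: list[float]
    iterations_run: int
    converged: bool
    failure: Optional[str] = None
    n_correspondences: int = 0


def find_correspondences(
    source: PointCloud | np.ndarray,
    target: PointCloud | np.ndarray,
    threshold: float,
    target_tree: Optional[cKDTree] = None,
) -> CorrespondenceSet:
    """Nearest target neighbour per source point, gated at strict < threshold."""
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    src = source.points if isinstance(source, PointCloud) else np.asarray(source)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target)
    tree = target_tree if target_tree is not None else cKDTree(tgt)
    dist, idx = tree.query(src, distance_upper_bound=threshold)
    keep = dist < threshold  # strict gate; unmatched entries come back as inf
    return CorrespondenceSet(idx[keep], np.nonzero(keep)[0], dist[keep], threshold)


def estimate_normals(cloud: PointCloud, k: int = 20, orient_toward: Optional[np.ndarray] = None) -> PointCloud:
    """Local-PCA surface normals over k neighbours.

    Each normal is the smallest-eigenvalue eigenvector of the neighbourhood
    covariance. Orientation: toward ``orient_toward`` if given, else away
    from the cloud centroid (outward for star-shaped surfaces). For the
    squared point-to-plane residual the sign is immaterial.
    """
    pts = cloud.points
    k = min(k, len(pts))
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    neigh = pts[idx]  # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    ref = orient_toward if orient_toward is not None else None
    if ref is None:
        outward = pts - pts.mean(axis=0)
        flip = np.einsum("ni,ni->n", normals, outward) < 0
    else:
        toward = np.asarray(ref, dtype=np.float64) - pts
        flip = np.einsum("ni,ni->n", normals, toward) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts, normals=normals, colors=cloud.colors)


def solve_point_to_point(
    corr: CorrespondenceSet, source: PointCloud | np.ndarray, target: PointCloud | np.ndarray
) -> RigidTransform:
    """Closed-form least-squares rigid minimizer of Σ‖p − Tq‖².

    Centroid alignment plus SVD of the cross-covariance, with the usual
    reflection correction.
    """
    src = source.points if isinstance(source, PointCloud) else np.asarray(source)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target)
    if len(corr) < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    q = src[corr.source_indices]
    p = tgt[corr.target_indices]
    q_bar, p_bar = q.mean(axis=0), p.mean(axis=0)
    h = (q - q_bar).T @ (p - p_bar)
    u, s, vt = np.linalg.svd(h)
    # rank < 2 leaves a rotation axis unconstrained
    if np.sum(s > max(s[0], 1e-300) * 1e-9) < 2:
        raise DegenerateGeometryError("correspondence geometry is rank-deficient")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = p_bar - r @ q_bar
    return RigidTransform.from_rotation_translation(r, t)


def solve_point_to_plane(
    corr: CorrespondenceSet, source: PointCloud | np.ndarray, target: PointCloud
) -> RigidTransform:
    """Minimize Σ((p − Tq)·n_p)² via small-angle linearization.

    The 6-vector (ω, t) solves the normal equations of the linearized
    residual; R = exp([ω]×) restores a proper rotation.
    """
    if not isinstance(target, PointCloud) or target.normals is None:
        raise InvalidInputError("point-to-plane requires target normals")
    src = source.points if isinstance(source, PointCloud) else np.asarray(source)
    if len(corr) < 6:
        raise DegenerateGeometryError("need at least 6 correspondences")
    q = src[corr.source_indices]
    p = target.points[corr.target_indices]
    n = target.normals[corr.target_indices]
    a = np.hstack([np.cross(q, n), n])  # (|K|, 6)
    b = np.einsum("ni,ni->n", n, p - q)
    # minimum-norm least squares: a rank-deficient system (e.g. a purely
    # planar target, which leaves in-plane sliding and in-plane rotation
    # unpenalized) gets zero motion along the unconstrained directions
    xi, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if not np.isfinite(xi).all() or rank < 1:
        raise DegenerateGeometryError("point-to-plane system is singular")
    r = Rotation.from_rotvec(xi[:3]).as_matrix()
    return RigidTransform.from_rotation_translation(r, xi[3:])


def _objective(src_pts: np.ndarray, target: PointCloud, corr: CorrespondenceSet, variant: str) -> float:
    """Per-correspondence mean of the ICP objective at the current pose."""
    p = target.points[corr.target_indices]
    q = src_pts[corr.source_indices]
    if variant == "point-to-plane":
        n = target.normals[corr.target_indices]
        res = np.einsum("ni,ni->n", p - q, n)
        return float(np.mean(res**2))
    return float(np.mean(np.sum((p - q) ** 2, axis=1)))


def run_icp(
    source: PointCloud,
    target: PointCloud,
    init: Optional[RigidTransform] = None,
    config: Optional[ICPConfig] = None,
    target_tree: Optional[cKDTree] = None,
) -> ICPResult:
    """Iterate correspondence search and transform estimation.

    Returns the composed transform (init included), the objective trace (one
    mean-residual value per iteration, evaluated after the update), and
    convergence flags. Zero correspondences at any iteration return the best
    state so far with a failure message.
    """
    if config is None:
        raise InvalidInputError("an ICPConfig (with a threshold) is required")
    if config.variant == "point-to-plane" and target.normals is None:
        raise InvalidInputError("point-to-plane ICP requires target normals")
    init = init or RigidTransform.identity()
    tree = target_tree if target_tree is not None else cKDTree(target.points)
    src_pts = init.transform_points(source.points)
    total = init
    trace: list[float] = []
    prev_e: Optional[float] = None
    converged = False
    n_corr = 0
    for it in range(config.max_iterations):
        corr = find_correspondences(src_pts, target.points, config.threshold, target_tree=tree)
        if len(corr) == 0:
            return ICPResult(total, trace, it, False, failure="zero correspondences", n_correspondences=0)
        try:
            if config.variant == "point-to-plane":
                inc = solve_point_to_plane(corr, src_pts, target)
            else:
                inc = solve_point_to_point(corr, src_pts, target)
        except DegenerateGeometryError as exc:
            return ICPResult(total, trace, it, False, failure=str(exc), n_correspondences=len(corr))
        src_pts = inc.transform_points(src_pts)
        total = inc @ total
        n_corr = len(corr)
        e = _objective(src_pts, target, corr, config.variant)
        trace.append(e)
        if prev_e is not None and abs(prev_e - e) < config.rel_change_tol * max(prev_e, 1e-300):
            converged = True
            break
        prev_e = e
    return ICPResult(total, trace, len(trace), converged, n_correspondences=n_corr)
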