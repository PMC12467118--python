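"""Registration quality metrics and the jet-colormap error field.

* fitness — fraction of source points whose nearest target neighbour (after
  applying the transform) lies within the inlier cutoff (0.5 mm default);
  an overlap measure, inherently small when a partial face scan is matched
  against a full-head CBCT surface.
* inlier RMSE — root mean square nearest-neighbour distance over inliers
  only (undefined, not zero, when there are no inliers).
* 95th-percentile error and Hausdorff distance — directed source→target by
  default; more sensitive to local misalignment than the inlier metrics.
* error field — per-point distances clamped to a cap (5.0 mm default) and
  mapped through the jet colormap (dark blue = 0, dark red ≥ cap).

The inlier rule uses a strict ``< cutoff`` comparison; ``cutoff`` is
configurable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from matplotlib import colormaps
from scipy.spatial import cKDTree

from .exceptions import InvalidInputError, ZeroInlierError
from .geometry import PointCloud, RigidTransform

__all__ = [
    "EvaluationReport",
    "ErrorField",
    "nearest_distances",
    "fitness",
    "inlier_rmse",
    "hausdorff_and_p95",
    "error_field",
    "evaluate",
]

DEFAULT_INLIER_CUTOFF = 0.5  # mm
DEFAULT_ERROR_CAP = 5.0  # mm


@dataclass(frozen=True)
class EvaluationReport:
    fitness: float
    inlier_rmse: float
    p95_error: float
    hausdorff: float
    n_inliers: int
    inlier_cutoff: float = DEFAULT_INLIER_CUTOFF

    def as_dict(self) -> dict:
        return {
            "fitness": self.fitness,
            "inlier_rmse_mm": self.inlier_rmse,
            "p95_error_mm": self.p95_error,
            "hausdorff_mm": self.hausdorff,
            "n_inliers": self.n_inliers,
            "inlier_cutoff_mm": self.inlier_cutoff,
        }


@dataclass
class ErrorField:
    distances: np.ndarray  # per-source-point nearest-neighbour distance, mm
    colors: np.ndarray  # N×3 RGB in [0, 1], jet
    cap: float = DEFAULT_ERROR_CAP


def nearest_distances(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    target_tree: Optional[cKDTree] = None,
) -> np.ndarray:
    """Directed nearest-neighbour distances transformed-source → target."""
    pts = source.points if transform is None else transform.transform_points(source.points)
    tree = target_tree if target_tree is not None else cKDTree(target.points)
    dist, _ = tree.query(pts)
    return dist


def fitness(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    cutoff: float = DEFAULT_INLIER_CUTOFF,
    target_tree: Optional[cKDTree] = None,
) -> float:
    """Inlier correspondences / number of source points."""
    if cutoff <= 0:
        raise InvalidInputError("inlier cutoff must be positive")
    dist = nearest_distances(source, target, transform, target_tree)
    return float(np.count_nonzero(dist < cutoff)) / len(source)


def inlier_rmse(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    cutoff: float = DEFAULT_INLIER_CUTOFF,
    target_tree: Optional[cKDTree] = None,
) -> float:
    """Root mean square nearest-neighbour distance over inlier pairs only."""
    if cutoff <= 0:
        raise InvalidInputError("inlier cutoff must be positive")
    dist = nearest_distances(source, target, transform, target_tree)
    inliers = dist[dist < cutoff]
    if inliers.size == 0:
        raise ZeroInlierError("no inlier correspondences; inlier RMSE undefined")
    return float(np.sqrt(np.mean(inliers**2)))


def hausdorff_and_p95(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    region_mask: Optional[np.ndarray] = None,
    symmetric: bool = False,
) -> tuple[float, float]:
    """(Hausdorff, 95th-percentile) of directed source→target distances.

    ``region_mask`` restricts the source points considered (e.g. a nasal or
    perioral sub-region); ``symmetric=True`` takes the max over both
    directions for the Hausdorff term and pools distances for the percentile.
    """
    dist = nearest_distances(source, target, transform)
    if region_mask is not None:
        dist = dist[np.asarray(region_mask, dtype=bool)]
        if dist.size == 0:
            raise InvalidInputError("region mask selects no points")
    if symmetric:
        inv = transform.inverse() if transform is not None else None
        back = nearest_distances(target, source, inv)
        dist = np.concatenate([dist, back])
    return float(dist.max()), float(np.percentile(dist, 95.0))


def error_field(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    cap: float = DEFAULT_ERROR_CAP,
) -> ErrorField:
    """Per-point distance, clamped to [0, cap], through the jet colormap."""
    if cap <= 0:
        raise InvalidInputError("error cap must be positive")
    dist = nearest_distances(source, target, transform)
    clamped = np.clip(dist, 0.0, cap)
    colors = colormaps["jet"](clamped / cap)[:, :3]
    return ErrorField(distances=dist, colors=colors, cap=cap)


def evaluate(
    source: PointCloud,
    target: PointCloud,
    transform: Optional[RigidTransform] = None,
    cutoff: float = DEFAULT_INLIER_CUTOFF,
    target_tree: Optional[cKDTree] = None,
) -> EvaluationReport:
    """All scalar metrics in one pass over the nearest-neighbour distances."""
    dist = nearest_distances(source, target, transform, target_tree)
    inliers = dist[dist < cutoff]
    if inliers.size == 0:
        raise ZeroInlierError("no inlier correspondences; evaluation undefined")
    return EvaluationReport(
        fitness=float(inliers.size) / len(source),
        inlier_rmse=float(np.sqrt(np.mean(inliers**2))),
        p95_error=float(np.percentile(dist, 95.0)),
        hausdorff=float(dist.max()),
        n_inliers=int(inliers.size),
        inlier_cutoff=cutoff,
    )
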