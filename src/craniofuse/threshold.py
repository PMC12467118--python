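"""Fitness-maximizing correspondence-threshold search and voxel downsampling.

The fitness-versus-threshold curve of threshold-gated ICP is empirically
unimodal: descending from a large threshold, fitness rises as outlier pairs
stop polluting the estimate, then collapses to zero once the threshold drops
below the noise/discretization floor. The search exploits this: run full ICP
at thresholds 10, 9, 8, … (same initialization every time) while fitness is
non-decreasing; at the first decline, probe ±0.5 around the best coarse
threshold and return the fitness argmax among the evaluated candidates.
Ties break toward lower inlier RMSE, then lower threshold. If the coarse
descent reaches 1 without declining it is extended to the 0.5 floor. The
search never evaluates outside [0.5, 10.0] and needs far fewer ICP runs than
an exhaustive 0.5-step sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InvalidInputError, RegistrationFailedError
from .geometry import PointCloud, RigidTransform
from .icp import ICPConfig, ICPResult, run_icp
from .metrics import DEFAULT_INLIER_CUTOFF, nearest_distances

__all__ = [
    "SearchTrace",
    "ThresholdEvaluation",
    "voxel_downsample",
    "choose_voxel",
    "search_optimal_threshold",
]

THRESHOLD_MIN = 0.5
THRESHOLD_MAX = 10.0
COARSE_STEP = 1.0
FINE_STEP = 0.5


@dataclass
class ThresholdEvaluation:
    """One ICP run at a fixed correspondence threshold."""

    threshold: float
    fitness: float
    inlier_rmse: float  # nan when no inliers
    result: Optional[ICPResult] = None


@dataclass
class SearchTrace:
    thresholds: list[float] = field(default_factory=list)
    fitness: list[float] = field(default_factory=list)
    inlier_rmse: list[float] = field(default_factory=list)
    chosen_threshold: float = float("nan")

    def record(self, ev: ThresholdEvaluation) -> None:
        self.thresholds.append(ev.threshold)
        self.fitness.append(ev.fitness)
        self.inlier_rmse.append(ev.inlier_rmse)

    @property
    def n_evaluations(self) -> int:
        return len(self.thresholds)


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """One representative point (member centroid) per occupied voxel.

    The grid is anchored at the cloud's minimum corner. Normals are averaged
    and renormalized, colors averaged.
    """
    if voxel <= 0:
        raise InvalidInputError("voxel size must be positive")
    pts = cloud.points
    keys = np.floor((pts - pts.min(axis=0)) / voxel).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_vox = counts.shape[0]

    def _mean(values: np.ndarray) -> np.ndarray:
        acc = np.zeros((n_vox, values.shape[1]))
        np.add.at(acc, inverse, values)
        return acc / counts[:, None]

    new_pts = _mean(pts)
    normals = None
    if cloud.normals is not None:
        normals = _mean(cloud.normals)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        normals /= norm
    colors = None if cloud.colors is None else np.clip(_mean(cloud.colors), 0.0, 1.0)
    return PointCloud(new_pts, normals=normals, colors=colors)


def choose_voxel(
    cloud: PointCloud,
    voxel_min: float = 0.5,
    voxel_max: float = 1.5,
    target_min: int = 20_000,
    target_max: int = 80_000,
) -> float:
    """Pick a voxel in [0.5, 1.5] mm giving 20k–80k downsampled points.

    Clamped to the range endpoints when even those cannot reach the count
    band (very sparse or very dense inputs). Bisection on the monotone
    count-versus-voxel relation.
    """
    if len(cloud) < 100:
        raise InvalidInputError("choose_voxel expects at least 100 points")

    def count(v: float) -> int:
        return len(voxel_downsample(cloud, v))

    if count(voxel_min) <= target_max:
        return voxel_min  # coarser would only lose points
    n_max = count(voxel_max)
    if n_max > target_max:
        return voxel_max  # even the coarsest voxel leaves too many points
    if n_max >= target_min:
        return voxel_max
    lo, hi = voxel_min, voxel_max
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        n = count(mid)
        if target_min <= n <= target_max:
            return mid
        if n > target_max:
            lo = mid  # too many points -> larger voxel
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _default_evaluator(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform,
    base: ICPConfig,
    cutoff: float,
    eval_source: Optional[PointCloud] = None,
    eval_target: Optional[PointCloud] = None,
) -> Callable[[float], ThresholdEvaluation]:
    """ICP on (source, target); fitness/inlier-RMSE on (eval_source, eval_target).

    The evaluation clouds default to the ICP clouds but are typically the
    full-resolution ones: the sub-millimetre inlier cutoff only
    discriminates at a sampling density finer than itself. Metric results
    are cached per resulting transform — different thresholds frequently
    converge to the identical alignment.
    """
    tree = cKDTree(target.points)
    ev_src = eval_source if eval_source is not None else source
    ev_tgt = eval_target if eval_target is not None else target
    ev_tree = tree if ev_tgt is target else cKDTree(ev_tgt.points)
    metric_cache: dict[bytes, tuple[float, float]] = {}

    def evaluate(threshold: float) -> ThresholdEvaluation:
        cfg = ICPConfig(
            threshold=threshold,
            max_iterations=base.max_iterations,
            rel_change_tol=base.rel_change_tol,
            variant=base.variant,
        )
        result = run_icp(source, target, init=init, config=cfg, target_tree=tree)
        key = np.round(result.transform.matrix, 9).tobytes()
        if key not in metric_cache:
            dist = nearest_distances(ev_src, ev_tgt, result.transform, target_tree=ev_tree)
            inliers = dist[dist < cutoff]
            fit = float(inliers.size) / len(ev_src)
            rmse = float(np.sqrt(np.mean(inliers**2))) if inliers.size else float("nan")
            metric_cache[key] = (fit, rmse)
        fit, rmse = metric_cache[key]
        return ThresholdEvaluation(threshold, fit, rmse, result)

    return evaluate


def search_optimal_threshold(
    source: Optional[PointCloud] = None,
    target: Optional[PointCloud] = None,
    init: Optional[RigidTransform] = None,
    icp_config_base: Optional[ICPConfig] = None,
    inlier_cutoff: float = DEFAULT_INLIER_CUTOFF,
    threshold_min: float = THRESHOLD_MIN,
    threshold_max: float = THRESHOLD_MAX,
    coarse_step: float = COARSE_STEP,
    fine_step: float = FINE_STEP,
    evaluate_fn: Optional[Callable[[float], ThresholdEvaluation]] = None,
    eval_source: Optional[PointCloud] = None,
    eval_target: Optional[PointCloud] = None,
    decline_rtol: float = 0.05,
    decline_atol: float = 0.02,
) -> tuple[SearchTrace, ThresholdEvaluation]:
    """Coarse descending sweep with fitness monitoring, then ±0.5 refinement.

    ``evaluate_fn`` (threshold → ThresholdEvaluation) makes the search logic
    testable against mocked registration backends; by default it runs full
    ICP from the same initialization at every threshold, scoring fitness on
    ``eval_source``/``eval_target`` (the full-resolution clouds) when given.
    """
    if evaluate_fn is None:
        if source is None or target is None:
            raise InvalidInputError("source/target clouds required without an evaluate_fn")
        if icp_config_base is None:
            icp_config_base = ICPConfig(threshold=threshold_max)
        evaluate_fn = _default_evaluator(
            source,
            target,
            init or RigidTransform.identity(),
            icp_config_base,
            inlier_cutoff,
            eval_source=eval_source,
            eval_target=eval_target,
        )

    trace = SearchTrace()
    cache: dict[float, ThresholdEvaluation] = {}

    def evaluate(threshold: float) -> ThresholdEvaluation:
        threshold = round(threshold, 6)
        if threshold not in cache:
            ev = evaluate_fn(threshold)
            cache[threshold] = ev
            trace.record(ev)
        return cache[threshold]

    def significant_decline(best_fit: float, fit: float) -> bool:
        # the pre-peak plateau carries run-to-run fitness noise; only a
        # decline clearly beyond it marks the peak
        return best_fit - fit > max(decline_rtol * best_fit, decline_atol)

    # coarse descent: 10, 9, 8, ... while fitness keeps (about) non-decreasing
    best = evaluate(threshold_max)
    t = threshold_max - coarse_step
    declined = False
    while t >= 1.0 - 1e-9:
        ev = evaluate(t)
        if significant_decline(best.fitness, ev.fitness):
            declined = True
            break
        if ev.fitness >= best.fitness:
            best = ev
        t -= coarse_step
    if not declined and best.threshold > threshold_min:
        ev = evaluate(threshold_min)  # protocol floor: extend 1.0 -> 0.5
        if ev.fitness >= best.fitness:
            best = ev

    # local refinement around the best coarse threshold
    candidates = [best]
    for probe in (best.threshold + fine_step, best.threshold - fine_step):
        if threshold_min - 1e-9 <= probe <= threshold_max + 1e-9:
            candidates.append(evaluate(probe))

    def sort_key(ev: ThresholdEvaluation):
        rmse = ev.inlier_rmse if np.isfinite(ev.inlier_rmse) else np.inf
        return (-ev.fitness, rmse, ev.threshold)

    chosen = min(candidates, key=sort_key)
    if chosen.fitness <= 0.0:
        raise RegistrationFailedError("fitness is zero at every evaluated threshold")
    trace.chosen_threshold = chosen.threshold
    return trace, chosen
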