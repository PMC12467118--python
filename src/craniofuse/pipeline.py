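"""End-to-end registration pipeline: center → pose-normalize → ICP + search.

Both surfaces are centered at the standard camera distance (d = 300 mm) and
independently driven to the same canonical frontal pose by the landmark
P-controller; this places them in a shared coordinate frame. The face scan
(source) is then refined onto the CBCT surface (target) by point-to-plane
ICP, with the correspondence threshold picked by the fitness-maximizing
search on voxel-downsampled copies. Final quality metrics are recomputed on
the full-resolution clouds; the reported transform maps the scan's original
frame into the CBCT's original frame.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import RegistrationFailedError
from .geometry import PointCloud, RigidTransform, center_at_depth, compose
from .icp import ICPConfig, estimate_normals
from .metrics import DEFAULT_ERROR_CAP, DEFAULT_INLIER_CUTOFF, EvaluationReport, evaluate
from .pose import (
    DEFAULT_GAIN,
    DEFAULT_MAX_ITERS,
    DEFAULT_THRESH_ANGLE,
    DEFAULT_THRESH_POS,
    LandmarkProvider,
    PoseResult,
    PoseTarget,
    default_pose_target,
    normalize_pose,
)
from .projection import CameraModel
from .threshold import SearchTrace, choose_voxel, search_optimal_threshold, voxel_downsample

__all__ = ["PipelineConfig", "RegistrationReport", "register_clouds"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the standard protocol.

    Defaults: camera distance d = 300 mm, controller gain p = 0.01, ICP
    capped at 30 iterations with relative objective tolerance 1e-6,
    threshold search over [0.5, 10.0] mm, inlier cutoff 0.5 mm, error-field
    cap 5.0 mm.
    """

    camera: CameraModel = field(default_factory=CameraModel)
    camera_distance_mm: float = 300.0
    gain: float = DEFAULT_GAIN
    pose_target: Optional[PoseTarget] = None  # None -> default for camera
    thresh_angle: float = DEFAULT_THRESH_ANGLE
    thresh_pos: float = DEFAULT_THRESH_POS
    max_pose_iters: int = DEFAULT_MAX_ITERS
    icp_max_iterations: int = 30
    icp_rel_change_tol: float = 1e-6
    icp_variant: str = "point-to-plane"
    threshold_min: float = 0.5
    threshold_max: float = 10.0
    coarse_step: float = 1.0
    fine_step: float = 0.5
    inlier_cutoff_mm: float = DEFAULT_INLIER_CUTOFF
    error_cap_mm: float = DEFAULT_ERROR_CAP
    normal_k: int = 20

    def resolved_target(self) -> PoseTarget:
        return self.pose_target or default_pose_target(self.camera)


@dataclass
class RegistrationReport:
    """Everything the registration produced, Table-style metrics included."""

    transform: RigidTransform  # scan original frame -> CBCT original frame
    icp_transform: RigidTransform  # canonical scan -> canonical CBCT
    cbct_canonical_transform: RigidTransform
    scan_canonical_transform: RigidTransform
    optimal_threshold: float
    evaluation: EvaluationReport
    search_trace: SearchTrace
    cbct_pose: PoseResult
    scan_pose: PoseResult
    voxel_size_mm: float
    timings_s: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "transform": self.transform.matrix.tolist(),
            "icp_transform": self.icp_transform.matrix.tolist(),
            "optimal_threshold_mm": self.optimal_threshold,
            **self.evaluation.as_dict(),
            "voxel_size_mm": self.voxel_size_mm,
            "pose_iterations": {
                "cbct": self.cbct_pose.iterations,
                "scan": self.scan_pose.iterations,
            },
            "pose_converged": {
                "cbct": self.cbct_pose.converged,
                "scan": self.scan_pose.converged,
            },
            "search": {
                "thresholds": self.search_trace.thresholds,
                "fitness": self.search_trace.fitness,
                "inlier_rmse": self.search_trace.inlier_rmse,
            },
            "timings_s": self.timings_s,
        }


def register_clouds(
    cbct: PointCloud,
    scan: PointCloud,
    cbct_provider: LandmarkProvider,
    scan_provider: LandmarkProvider,
    config: Optional[PipelineConfig] = None,
) -> RegistrationReport:
    """Run the full two-stage registration (scan → CBCT).

    The providers supply face-mesh landmarks for the respective rendered
    views (a detector adapter, a landmark-JSON replay provider, or the
    synthetic oracle).
    """
    cfg = config or PipelineConfig()
    target_pose = cfg.resolved_target()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    cbct_centered, t_center_cbct = center_at_depth(cbct, cfg.camera_distance_mm)
    scan_centered, t_center_scan = center_at_depth(scan, cfg.camera_distance_mm)

    pose_kwargs = dict(
        target=target_pose,
        gain=cfg.gain,
        thresh_angle=cfg.thresh_angle,
        thresh_pos=cfg.thresh_pos,
        max_iters=cfg.max_pose_iters,
    )
    cbct_pose = normalize_pose(cbct_centered, cfg.camera, cbct_provider, **pose_kwargs)
    scan_pose = normalize_pose(scan_centered, cfg.camera, scan_provider, **pose_kwargs)
    timings["pose_initialization"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cbct_canonical = cbct_pose.cloud
    scan_canonical = scan_pose.cloud
    voxel = choose_voxel(cbct_canonical) if len(cbct_canonical) >= 100 else 0.5
    cbct_ds = estimate_normals(voxel_downsample(cbct_canonical, voxel), k=cfg.normal_k)
    scan_ds = voxel_downsample(scan_canonical, voxel)
    timings["downsample_normals"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    base = ICPConfig(
        threshold=cfg.threshold_max,
        max_iterations=cfg.icp_max_iterations,
        rel_change_tol=cfg.icp_rel_change_tol,
        variant=cfg.icp_variant,  # type: ignore[arg-type]
    )
    trace, chosen = search_optimal_threshold(
        scan_ds,
        cbct_ds,
        init=RigidTransform.identity(),
        icp_config_base=base,
        inlier_cutoff=cfg.inlier_cutoff_mm,
        threshold_min=cfg.threshold_min,
        threshold_max=cfg.threshold_max,
        coarse_step=cfg.coarse_step,
        fine_step=cfg.fine_step,
        eval_source=scan_canonical,
        eval_target=cbct_canonical,
    )
    timings["icp_refinement"] = time.perf_counter() - t0
    if chosen.result is None:  # pragma: no cover - default evaluator always sets it
        raise RegistrationFailedError("threshold search returned no ICP result")
    icp_transform = chosen.result.transform

    t0 = time.perf_counter()
    evaluation = evaluate(
        scan_canonical, cbct_canonical, icp_transform, cutoff=cfg.inlier_cutoff_mm
    )
    timings["evaluation"] = time.perf_counter() - t0

    t_cbct = compose([cbct_pose.transform, t_center_cbct])
    t_scan = compose([scan_pose.transform, t_center_scan])
    total = compose([t_cbct.inverse(), icp_transform, t_scan])

    return RegistrationReport(
        transform=total,
        icp_transform=icp_transform,
        cbct_canonical_transform=t_cbct,
        scan_canonical_transform=t_scan,
        optimal_threshold=chosen.threshold,
        evaluation=evaluation,
        search_trace=trace,
        cbct_pose=cbct_pose,
        scan_pose=scan_pose,
        voxel_size_mm=voxel,
        timings_s=timings,
    )
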