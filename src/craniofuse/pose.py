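"""Landmark-driven pose descriptors and the P-controller normalization loop.

A head cloud is driven to a canonical frontal pose by iterating:
render → detect face-mesh landmarks → compute pose descriptors
(roll/yaw/pitch, nose position, apparent face width) → proportional
corrections → build a rigid update → apply. Both modalities (CBCT soft-tissue
surface and face scan) are driven to the *same* target, which places them in
a shared coordinate frame before ICP refinement.

Landmark (detector-frame) convention
------------------------------------
``FaceLandmarks`` holds, per canonical face-mesh index:

* ``x``, ``y`` — pixel coordinates in the rendered view;
* ``z``       — forward protrusion relative to the mean depth of the six
  lateral landmarks, converted to the pixel scale at the landmark's own
  depth: ``z_i = (d̄_lateral − d_i) · f / d_i``.

This is the relative-depth convention of dense face-mesh detectors (z is on
the same scale as x and y, positive toward the camera), and it makes the
yaw/pitch descriptors approximate the true head angles, so the controller
error contracts by ≈ (1 − gain) per iteration.

Required canonical indices: 162/234/132 (subject's one side), 389/454/361
(other side), 19 (nose). Outer eye corners are 162 and 389; 234 and 454 span
the facial width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Protocol

import numpy as np

from .exceptions import DetectionFailureError, InvalidInputError
from .geometry import (
    EulerAngles,
    PointCloud,
    RigidTransform,
    apply,
    centroid,
    euler_to_rotation,
)
from .projection import CameraModel, RenderedView, render

__all__ = [
    "REQUIRED_LANDMARKS",
    "LATERAL_LANDMARKS",
    "FaceLandmarks",
    "PoseDescriptor",
    "PoseTarget",
    "LandmarkProvider",
    "detector_frame",
    "compute_roll",
    "compute_yaw_pitch",
    "compute_face_width",
    "describe_pose",
    "pose_error",
    "controller_step",
    "PoseIteration",
    "PoseResult",
    "default_pose_target",
    "normalize_pose",
]

NOSE = 19
LEFT_EYE_OUTER, RIGHT_EYE_OUTER = 162, 389
WIDTH_LEFT, WIDTH_RIGHT = 234, 454
LATERAL_LANDMARKS = (162, 234, 132, 389, 454, 361)
REQUIRED_LANDMARKS = (19, 132, 162, 234, 361, 389, 454)

DEFAULT_GAIN = 0.01  # proportional gain p
DEFAULT_THRESH_ANGLE = 0.01  # rad, on sum|Δθ|
DEFAULT_THRESH_POS = 6.0  # px, on |Δx|+|Δy|+|ΔD|
DEFAULT_MAX_ITERS = 500


@dataclass
class FaceLandmarks:
    """Detector-frame landmark set keyed by canonical face-mesh index.

    ``anchor_mm`` optionally carries the absolute camera-frame 3D position of
    the nose (mm); pose updates rotate about it when present, keeping the
    face fixed under orientation corrections.
    """

    coords: Mapping[int, np.ndarray]
    anchor_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        coords = {int(k): np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.coords.items()}
        for idx in REQUIRED_LANDMARKS:
            if idx not in coords:
                raise InvalidInputError(f"required landmark {idx} missing")
            if not np.isfinite(coords[idx]).all():
                raise InvalidInputError(f"landmark {idx} has non-finite coordinates")
        self.coords = coords

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.coords[idx]


@dataclass(frozen=True)
class PoseDescriptor:
    """Measured pose: angles in radians, nose position and face width in px."""

    theta_z_roll: float
    theta_y_yaw: float
    theta_x_pitch: float
    x: float
    y: float
    D: float


@dataclass(frozen=True)
class PoseTarget:
    """Target pose the controller drives both modalities toward."""

    theta_z_0: float = 0.0
    theta_y_0: float = 0.0
    theta_x_0: float = 0.0
    x0: float = 320.0
    y0: float = 240.0
    D0: float = 288.0

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise InvalidInputError("target face width D0 must be positive")


def default_pose_target(camera: CameraModel) -> PoseTarget:
    """Frontal pose, nose at the principal point, width 0.45× the frame."""
    return PoseTarget(
        x0=camera.principal_point[0],
        y0=camera.principal_point[1],
        D0=0.45 * camera.image_width_px,
    )


class LandmarkProvider(Protocol):
    """Contract: a rendered view in, detector-frame landmarks out.

    Implementations must be deterministic for a fixed view and raise
    :class:`DetectionFailureError` when no face can be detected.
    """

    def detect(self, view: RenderedView) -> FaceLandmarks: ...


def detector_frame(raw: Mapping[int, np.ndarray], camera: CameraModel) -> FaceLandmarks:
    """Convert raw (u px, v px, depth mm) landmarks to the detector frame.

    Depth becomes protrusion relative to the mean lateral-landmark depth,
    scaled to pixels at each landmark's own depth.
    """
    raw = {int(k): np.asarray(v, dtype=np.float64).reshape(3) for k, v in raw.items()}
    lateral_depths = [raw[i][2] for i in LATERAL_LANDMARKS if i in raw]
    if len(lateral_depths) < len(LATERAL_LANDMARKS):
        raise InvalidInputError("all six lateral landmarks are required")
    d_ref = float(np.mean(lateral_depths))
    out = {}
    for idx, (u, v, d) in ((k, tuple(p)) for k, p in raw.items()):
        if d <= 0:
            raise InvalidInputError(f"landmark {idx} has non-positive depth")
        out[idx] = np.array([u, v, (d_ref - d) * camera.focal_length_px / d])
    u_n, v_n, d_n = raw[NOSE]
    anchor = np.array(
        [
            (u_n - camera.principal_point[0]) * d_n / camera.focal_length_px,
            (v_n - camera.principal_point[1]) * d_n / camera.focal_length_px,
            d_n,
        ]
    )
    return FaceLandmarks(out, anchor_mm=anchor)


def compute_roll(lm: FaceLandmarks) -> float:
    """Roll from the slope of the outer-eye-corner line (landmarks 162→389)."""
    p_l, p_r = lm[LEFT_EYE_OUTER], lm[RIGHT_EYE_OUTER]
    dx = p_r[0] - p_l[0]
    if dx == 0.0:
        raise DetectionFailureError("eye corners vertically aligned; roll undefined")
    return float(np.arctan((p_r[1] - p_l[1]) / dx))


def compute_yaw_pitch(lm: FaceLandmarks) -> tuple[float, float]:
    """Yaw and pitch from the nose against the six lateral landmarks.

    ``yaw = arctan((x19 − x̄)/z19)``, ``pitch = arctan((y19 − ȳ)/z19)`` with
    x̄, ȳ the lateral-landmark means and z19 the nose protrusion.
    """
    lateral = np.array([lm[i] for i in LATERAL_LANDMARKS])
    x_bar, y_bar = lateral[:, 0].mean(), lateral[:, 1].mean()
    nose = lm[NOSE]
    z19 = nose[2]
    if z19 <= 0:
        raise DetectionFailureError("nose protrusion non-positive; face turned away")
    yaw = float(np.arctan((nose[0] - x_bar) / z19))
    pitch = float(np.arctan((nose[1] - y_bar) / z19))
    return yaw, pitch


def compute_face_width(lm: FaceLandmarks) -> float:
    """3D Euclidean distance between the width landmarks 234 and 454."""
    return float(np.linalg.norm(lm[WIDTH_RIGHT] - lm[WIDTH_LEFT]))


def describe_pose(lm: FaceLandmarks) -> PoseDescriptor:
    roll = compute_roll(lm)
    yaw, pitch = compute_yaw_pitch(lm)
    width = compute_face_width(lm)
    nose = lm[NOSE]
    return PoseDescriptor(
        theta_z_roll=roll,
        theta_y_yaw=yaw,
        theta_x_pitch=pitch,
        x=float(nose[0]),
        y=float(nose[1]),
        D=width,
    )


def pose_error(pose: PoseDescriptor, target: PoseTarget) -> np.ndarray:
    """Δ = current − target, ordered (Δθz, Δθy, Δθx, Δx, Δy, ΔD)."""
    return np.array(
        [
            pose.theta_z_roll - target.theta_z_0,
            pose.theta_y_yaw - target.theta_y_0,
            pose.theta_x_pitch - target.theta_x_0,
            pose.x - target.x0,
            pose.y - target.y0,
            pose.D - target.D0,
        ]
    )


def controller_step(
    pose: PoseDescriptor, target: PoseTarget, gain: float = DEFAULT_GAIN
) -> tuple[EulerAngles, np.ndarray]:
    """Proportional corrections δ = −gain·Δ in descriptor units.

    Returns Euler-angle deltas (radians) and (δx, δy, δD) in pixels. The
    geometric interpretation (pixel→mm conversion, the yaw mirror and the
    D→z sign) is applied where the update matrix is built, in
    :func:`normalize_pose`.
    """
    if not (0.0 < gain < 1.0):
        raise InvalidInputError("controller gain must lie in (0, 1)")
    d = -gain * pose_error(pose, target)
    return EulerAngles(theta_x=d[2], theta_y=d[1], theta_z=d[0]), d[3:6]


@dataclass(frozen=True)
class PoseIteration:
    """One controller iteration: the measured errors before the update."""

    iteration: int
    errors: np.ndarray  # (Δθz, Δθy, Δθx, Δx, Δy, ΔD)

    @property
    def angle_error_sum(self) -> float:
        return float(np.abs(self.errors[:3]).sum())

    @property
    def position_error_sum(self) -> float:
        return float(np.abs(self.errors[3:]).sum())


@dataclass
class PoseResult:
    cloud: PointCloud
    transform: RigidTransform
    trace: list[PoseIteration]
    converged: bool
    failure: Optional[str] = None

    @property
    def iterations(self) -> int:
        return len(self.trace)


def _update_transform(
    deltas_angles: EulerAngles,
    deltas_pos_px: np.ndarray,
    center: np.ndarray,
    camera: CameraModel,
) -> RigidTransform:
    """Map controller deltas to a rigid update about ``center``.

    The rotation center is the detected nose position when the landmark set
    provides one (rotations then leave the face position untouched —
    decoupling orientation from position corrections), else the cloud
    centroid. The face points toward the camera (−z), so the image-measured
    yaw is the mirror of the camera-frame Ry angle; pixel nose deltas convert
    to mm at the center's depth; and an oversized face (ΔD > 0, δD < 0) must
    move away from the camera, +z.
    """
    angles = EulerAngles(
        theta_x=deltas_angles.theta_x,
        theta_y=-deltas_angles.theta_y,
        theta_z=deltas_angles.theta_z,
    )
    rotation = euler_to_rotation(angles)
    mm_per_px = center[2] / camera.focal_length_px
    t = np.array(
        [
            deltas_pos_px[0] * mm_per_px,
            deltas_pos_px[1] * mm_per_px,
            -deltas_pos_px[2],  # δD < 0 when face too large → +z motion
        ]
    )
    return RigidTransform.rotation_about(rotation, center, t)


def normalize_pose(
    cloud: PointCloud,
    camera: CameraModel,
    provider: LandmarkProvider,
    target: Optional[PoseTarget] = None,
    gain: float = DEFAULT_GAIN,
    thresh_angle: float = DEFAULT_THRESH_ANGLE,
    thresh_pos: float = DEFAULT_THRESH_POS,
    max_iters: int = DEFAULT_MAX_ITERS,
    splat_radius_px: int = 2,
    framing_step: bool = True,
) -> PoseResult:
    """Drive a (pre-centered) head cloud to the canonical frontal pose.

    Iterates render → detect → descriptors → P-controller → rigid update,
    accumulating the total transform, until both summed absolute angle errors
    fall below ``thresh_angle`` and summed position/size errors below
    ``thresh_pos``, or ``max_iters`` is hit (non-convergence is flagged, the
    best state is still returned). A mid-loop detection failure aborts with
    the last good state and a failure message.

    ``framing_step`` applies one full translation-only correction from the
    first detection (nose to the target position, face width to the target
    size) before the proportional loop starts. Centroid centering alone can
    leave a clutter-heavy scan (torso, clothing) framed far off-axis, where
    perspective couples the descriptors and slows the loop; the framing step
    realizes the "appropriate relative positioning between the data and the
    virtual camera" that landmark detection presumes, and is the identity
    when the face is already well framed.
    """
    if target is None:
        target = default_pose_target(camera)
    total = RigidTransform.identity()
    current = cloud
    trace: list[PoseIteration] = []

    def _anchor(lm: FaceLandmarks, cloud_: PointCloud) -> np.ndarray:
        return lm.anchor_mm if lm.anchor_mm is not None else centroid(cloud_)

    if framing_step:
        view = render(current, camera, splat_radius_px)
        lm = provider.detect(view)  # initial-view failure propagates
        pose = describe_pose(lm)
        errors = pose_error(pose, target)
        m = _update_transform(EulerAngles(), -errors[3:6], _anchor(lm, current), camera)
        current = apply(m, current)
        total = m @ total
    for i in range(max_iters):
        view = render(current, camera, splat_radius_px)
        try:
            lm = provider.detect(view)
            pose = describe_pose(lm)
        except DetectionFailureError as exc:
            if i == 0:
                raise
            return PoseResult(current, total, trace, converged=False, failure=str(exc))
        errors = pose_error(pose, target)
        trace.append(PoseIteration(i, errors))
        if np.abs(errors[:3]).sum() < thresh_angle and np.abs(errors[3:]).sum() < thresh_pos:
            return PoseResult(current, total, trace, converged=True)
        d_ang, d_pos = controller_step(pose, target, gain)
        m = _update_transform(d_ang, d_pos, _anchor(lm, current), camera)
        current = apply(m, current)
        total = m @ total
    return PoseResult(current, total, trace, converged=False, failure="max_iters reached")
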