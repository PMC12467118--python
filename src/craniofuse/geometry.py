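"""Rigid-body math and the point-cloud container.

Conventions (fixed for the whole package):

* right-handed coordinates, all lengths in millimetres;
* the virtual camera sits at the origin looking along +z, with +y up;
* a face presented to the camera therefore points along −z;
* Euler composition order is ``R = Rz(θz) · Ry(θy) · Rx(θx)``;
* ``compose([A, B])`` is the matrix product ``A @ B``: the last element of the
  list is applied to a cloud first, i.e. newly accumulated transforms go to
  the *left* ("left-multiply accumulates").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import EmptyCloudError, InvalidInputError

__all__ = [
    "PointCloud",
    "RigidTransform",
    "EulerAngles",
    "centroid",
    "center_at_depth",
    "euler_to_rotation",
    "euler_from_rotation",
    "compose",
    "apply",
    "rotation_angle_deg",
]



@dataclass
class PointCloud:
    """N 3D points in mm with optional unit normals and RGB colors in [0, 1]."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise EmptyCloudError("point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise InvalidInputError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise InvalidInputError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise InvalidInputError("normals must be unit length (±1e-6)")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != self.points.shape:
                raise InvalidInputError("colors must match points shape")
            if self.colors.min() < 0.0 or self.colors.max() > 1.0:
                raise InvalidInputError("colors must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def with_points(self, points: np.ndarray, normals: Optional[np.ndarray] = "keep") -> "PointCloud":  # type: ignore[assignment]
        """Copy carrying over per-point attributes (same N)."""
        if isinstance(normals, str):
            normals = self.normals
        return PointCloud(points, normals=normals, colors=self.colors)

    def select(self, index: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points[index],
            normals=None if self.normals is None else self.normals[index],
            colors=None if self.colors is None else self.colors[index],
        )


@dataclass(frozen=True)
class EulerAngles:
    """Rotations about the camera axes, radians: pitch θx, yaw θy, roll θz."""

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.theta_x, self.theta_y, self.theta_z):
            if not np.isfinite(v):
                raise InvalidInputError("Euler angles must be finite")


@dataclass(frozen=True)
class RigidTransform:
    """A 4×4 homogeneous rigid transform; rotation block in SO(3)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise InvalidInputError(f"transform matrix must be 4×4, got {m.shape}")
        if not np.array_equal(m[3], (0.0, 0.0, 0.0, 1.0)):
            m = m.copy()
            if not np.allclose(m[3], (0, 0, 0, 1), atol=1e-12):
                raise InvalidInputError("last row must be (0, 0, 0, 1)")
            m[3] = (0.0, 0.0, 0.0, 1.0)
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise InvalidInputError("rotation block must have det +1 (no reflection)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(4))

    @staticmethod
    def from_rotation_translation(rotation: np.ndarray, translation: Iterable[float]) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = np.asarray(tuple(translation), dtype=np.float64)
        return RigidTransform(m)

    @staticmethod
    def translation_only(translation: Iterable[float]) -> "RigidTransform":
        return RigidTransform.from_rotation_translation(np.eye(3), translation)

    @staticmethod
    def rotation_about(rotation: np.ndarray, center: np.ndarray, extra_translation: Iterable[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotate about ``center`` (not the origin), then translate."""
        center = np.asarray(center, dtype=np.float64)
        t = center + np.asarray(tuple(extra_translation), dtype=np.float64) - rotation @ center
        return RigidTransform.from_rotation_translation(rotation, t)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)


def centroid(cloud: PointCloud) -> np.ndarray:
    """Component-wise arithmetic mean of the points (Cx, Cy, Cz)."""
    return cloud.points.mean(axis=0)


def center_at_depth(cloud: PointCloud, d: float = 300.0) -> tuple[PointCloud, RigidTransform]:
    """Translate the cloud so its centroid sits at (0, 0, d) on the optical axis.

    ``d`` is the camera-to-cloud distance in mm (default 300). Returns the
    translated cloud and the pure translation applied.
    """
    if d <= 0:
        raise InvalidInputError("camera distance d must be positive")
    c = centroid(cloud)
    t = np.array([0.0, 0.0, d]) - c
    transform = RigidTransform.translation_only(t)
    return apply(transform, cloud), transform


def euler_to_rotation(angles: EulerAngles) -> np.ndarray:
    """Rz(θz)·Ry(θy)·Rx(θx) from elementary right-handed rotation matrices."""
    cx, sx = np.cos(angles.theta_x), np.sin(angles.theta_x)
    cy, sy = np.cos(angles.theta_y), np.sin(angles.theta_y)
    cz, sz = np.cos(angles.theta_z), np.sin(angles.theta_z)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_from_rotation(rotation: np.ndarray) -> EulerAngles:
    """Invert :func:`euler_to_rotation` for |θy| < π/2."""
    # R = Rz·Ry·Rx has R[2,0] = -sin(θy)
    theta_y = float(np.arcsin(np.clip(-rotation[2, 0], -1.0, 1.0)))
    theta_x = float(np.arctan2(rotation[2, 1], rotation[2, 2]))
    theta_z = float(np.arctan2(rotation[1, 0], rotation[0, 0]))
    return EulerAngles(theta_x=theta_x, theta_y=theta_y, theta_z=theta_z)


def compose(transforms: Sequence[RigidTransform]) -> RigidTransform:
    """Matrix product of the transforms: the LAST list element acts first.

    ``apply(compose([A, B]), cloud) == apply(A, apply(B, cloud))``.
    """
    if len(transforms) == 0:
        raise InvalidInputError("compose requires at least one transform")
    m = transforms[0].matrix
    for t in transforms[1:]:
        m = m @ t.matrix
    return RigidTransform(m)


def apply(transform: RigidTransform, cloud: PointCloud) -> PointCloud:
    """Map every point through the homogeneous transform; rotate normals by R."""
    pts = transform.transform_points(cloud.points)
    normals = None
    if cloud.normals is not None:
        normals = cloud.normals @ transform.rotation.T
    return PointCloud(pts, normals=normals, colors=cloud.colors)


def rotation_angle_deg(transform_or_rotation) -> float:
    """Geodesic rotation angle of a transform (or 3×3 matrix), in degrees."""
    r = transform_or_rotation.rotation if isinstance(transform_or_rotation, RigidTransform) else np.asarray(transform_or_rotation)
    cos_theta = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))
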