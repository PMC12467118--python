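"""Virtual pinhole camera: projection, z-buffer point splatting, depth lookup.

The camera is fixed at the origin looking along +z, matching the pose-
normalization geometry. Image coordinates follow the projection equations
``u = f·x/z + cx``, ``v = f·y/z + cy`` — note that with +y up in 3D, v grows
upward too; the convention is internal and consistent for both modalities,
which is all the pose loop requires.

Rasterization is z-buffer point splatting: each visible point paints a
``(2r+1)²`` pixel disc-bounding square, the nearest point wins each pixel and
exact depth ties go to the lower point index. Rendering is lazy: a
:class:`RenderedView` rasterizes on first access of ``image``/``depth``/
``point_index``, so providers that read only the 3D points (the synthetic
oracle) pay nothing for rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import FaceNotInViewError, InvalidInputError, LandmarkDepthMissingError
from .geometry import PointCloud

__all__ = ["CameraModel", "RenderedView", "project_points", "back_project", "render", "landmark_to_3d"]

_MIN_DEPTH = 1e-6
_DEFAULT_SKIN = (0.87, 0.72, 0.60)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics for the virtual camera.

    Defaults (640×480, f = 600 px, principal point at the image center) put a
    ~140 mm face at the standard 300 mm working distance across roughly half
    of the frame width, inside a typical face detector's operating range.
    """

    focal_length_px: float = 600.0
    image_width_px: int = 640
    image_height_px: int = 480
    principal_point: tuple[float, float] = (320.0, 240.0)

    def __post_init__(self) -> None:
        if self.focal_length_px <= 0:
            raise InvalidInputError("focal length must be positive")
        if self.image_width_px < 64 or self.image_height_px < 64:
            raise InvalidInputError("image dimensions must be at least 64 px")


def project_points(cloud: PointCloud | np.ndarray, camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Project points to pixel coordinates; flag visibility.

    Returns ``(uv, visible)`` where ``uv`` is N×2 and ``visible`` marks points
    in front of the camera and inside the frame. Raises
    :class:`FaceNotInViewError` if nothing is visible.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    z = pts[:, 2]
    in_front = z > _MIN_DEPTH
    zsafe = np.where(in_front, z, 1.0)
    u = camera.focal_length_px * pts[:, 0] / zsafe + camera.principal_point[0]
    v = camera.focal_length_px * pts[:, 1] / zsafe + camera.principal_point[1]
    uv = np.column_stack([u, v])
    visible = (
        in_front
        & (u >= 0.0)
        & (u < camera.image_width_px)
        & (v >= 0.0)
        & (v < camera.image_height_px)
    )
    if not visible.any():
        raise FaceNotInViewError("no point of the cloud projects inside the camera frame")
    return uv, visible


def back_project(uv: np.ndarray, depth: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Invert the pinhole projection at known depth (mm)."""
    uv = np.atleast_2d(np.asarray(uv, dtype=np.float64))
    depth = np.atleast_1d(np.asarray(depth, dtype=np.float64))
    x = (uv[:, 0] - camera.principal_point[0]) * depth / camera.focal_length_px
    y = (uv[:, 1] - camera.principal_point[1]) * depth / camera.focal_length_px
    return np.column_stack([x, y, depth])


class RenderedView:
    """Lazily rasterized view of a point cloud.

    Attributes ``image`` (H×W×3 float), ``depth`` (H×W mm, 0 = empty) and
    ``point_index`` (H×W int, −1 = empty) are computed on first access.
    ``points`` exposes the 3D points the view was made from, so landmark
    providers that track geometry directly never trigger rasterization.
    """

    def __init__(self, cloud: PointCloud, camera: CameraModel, splat_radius_px: int = 2) -> None:
        if splat_radius_px < 0:
            raise InvalidInputError("splat radius must be non-negative")
        self.cloud = cloud
        self.camera = camera
        self.splat_radius_px = int(splat_radius_px)
        self._image: Optional[np.ndarray] = None
        self._depth: Optional[np.ndarray] = None
        self._point_index: Optional[np.ndarray] = None

    @property
    def points(self) -> np.ndarray:
        return self.cloud.points

    def _rasterize(self) -> None:
        cam = self.camera
        h, w = cam.image_height_px, cam.image_width_px
        uv, visible = project_points(self.cloud, cam)
        idx = np.nonzero(visible)[0]
        z = self.cloud.points[idx, 2]
        px = np.floor(uv[idx]).astype(np.int64)

        r = self.splat_radius_px
        offs = np.stack(np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij"), axis=-1).reshape(-1, 2)
        # splat: (n_points, n_offsets, 2)
        cols = px[:, None, 0] + offs[None, :, 1]
        rows = px[:, None, 1] + offs[None, :, 0]
        flat_idx = np.repeat(idx, offs.shape[0])
        flat_z = np.repeat(z, offs.shape[0])
        rows, cols = rows.ravel(), cols.ravel()
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows, cols = rows[inside], cols[inside]
        flat_idx, flat_z = flat_idx[inside], flat_z[inside]

        # deterministic z-buffer reduction: per pixel, the nearest point wins
        # and exact depth ties go to the lower point index
        flat_pix = rows * w + cols
        order = np.lexsort((flat_idx, flat_z, flat_pix))
        flat_pix, flat_z, flat_idx = flat_pix[order], flat_z[order], flat_idx[order]
        uniq_pix, first = np.unique(flat_pix, return_index=True)

        depth = np.zeros((h, w), dtype=np.float64)
        point_index = np.full((h, w), -1, dtype=np.int64)
        depth.flat[uniq_pix] = flat_z[first]
        point_index.flat[uniq_pix] = flat_idx[first]

        image = np.zeros((h, w, 3), dtype=np.float64)
        covered = point_index >= 0
        if self.cloud.colors is not None:
            image[covered] = self.cloud.colors[point_index[covered]]
        else:
            image[covered] = _DEFAULT_SKIN
        self._image, self._depth, self._point_index = image, depth, point_index

    @property
    def image(self) -> np.ndarray:
        if self._image is None:
            self._rasterize()
        return self._image

    @property
    def depth(self) -> np.ndarray:
        if self._depth is None:
            self._rasterize()
        return self._depth

    @property
    def point_index(self) -> np.ndarray:
        if self._point_index is None:
            self._rasterize()
        return self._point_index


def render(cloud: PointCloud, camera: CameraModel, splat_radius_px: int = 2) -> RenderedView:
    """Create a (lazily rasterized) z-buffered view of the cloud."""
    return RenderedView(cloud, camera, splat_radius_px)


def landmark_to_3d(
    view: RenderedView,
    pixel: tuple[float, float] | np.ndarray,
    camera: Optional[CameraModel] = None,
    search_radius_px: int = 3,
) -> np.ndarray:
    """Lift a landmark pixel to (u, v, depth mm) using the rendered depth map.

    The depth is taken from the nearest covered pixel within
    ``search_radius_px``; raises :class:`LandmarkDepthMissingError` if none is
    covered.
    """
    cam = camera or view.camera
    u, v = float(pixel[0]), float(pixel[1])
    if not (0 <= u < cam.image_width_px and 0 <= v < cam.image_height_px):
        raise InvalidInputError(f"pixel ({u}, {v}) outside the image")
    depth_map = view.depth
    col0, row0 = int(np.floor(u)), int(np.floor(v))
    best = None
    r = int(search_radius_px)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            rr, cc = row0 + dr, col0 + dc
            if not (0 <= rr < cam.image_height_px and 0 <= cc < cam.image_width_px):
                continue
            if depth_map[rr, cc] <= 0:
                continue
            d2 = dr * dr + dc * dc
            if best is None or d2 < best[0]:
                best = (d2, depth_map[rr, cc])
    if best is None:
        raise LandmarkDepthMissingError(f"no covered pixel within {r} px of ({u:.1f}, {v:.1f})")
    return np.array([u, v, best[1]])
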