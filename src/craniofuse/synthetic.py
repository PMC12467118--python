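"""Synthetic head fixtures: surfaces, partial scans, ground truth, oracle landmarks.

Every stage of the registration pipeline is testable without patient data
through a seeded generator that emulates the acquisition geometry:

* :func:`make_head` — a closed, smooth head-like surface (superellipsoid
  skull with nose ridge, brow, eye sockets, cheekbones, chin and jaw bulges
  as radial displacement fields, plus seeded low-frequency shape variation)
  standing in for the CBCT soft-tissue isosurface, with the seven canonical
  face-mesh landmarks placed at their anatomical analogues.
* :func:`make_scan` — a single-viewpoint capture of that head: hidden-point
  removal from a camera 800 mm in front (azimuth 0/±30°), per-point Gaussian
  sensor noise, and content a structured-light scanner sees but CBCT does
  not — a hair-like shell offset over the non-face scalp and a torso/clothing
  slab below the chin. Only the facial region coincides with the head
  geometry, so the scan→head overlap fraction lands in the 15–25% regime
  characteristic of full-head-versus-face-scan fusion. A random rigid offset
  (≤ 30°, ≤ 50 mm) is applied and recorded as the ground-truth inverse.
* :func:`oracle_landmark_provider` — a LandmarkProvider that tracks the
  fixture's landmark points through every transform and reports them as a
  face-mesh detector would (pixel coordinates + relative depth), with
  optional detection jitter. It substitutes the pretrained detector in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .exceptions import DetectionFailureError, InvalidInputError
from .geometry import PointCloud, RigidTransform
from .pose import LATERAL_LANDMARKS, NOSE, REQUIRED_LANDMARKS, FaceLandmarks, detector_frame
from .projection import RenderedView

__all__ = [
    "HeadFixture",
    "make_head",
    "make_scan",
    "make_fixture",
    "OracleLandmarkProvider",
    "oracle_landmark_provider",
]

Direction = Literal["left", "center", "right"]

# landmark directions on the unit sphere, head frame (face toward −z, +y up)
_LANDMARK_DIRECTIONS: dict[int, tuple[float, float, float]] = {
    19: (0.0, -0.12, -1.0),
    162: (-0.52, 0.20, -0.80),
    389: (0.52, 0.20, -0.80),
    234: (-0.80, 0.05, -0.52),
    454: (0.80, 0.05, -0.52),
    132: (-0.62, -0.42, -0.62),
    361: (0.62, -0.42, -0.62),
}

_FACE_CAP_START_DEG = 62.0  # inside: exact skin, shared with CBCT
_FACE_CAP_END_DEG = 72.0  # beyond: full hair offset
_SCAN_DISTANCE_MM = 800.0
_MAX_INCIDENCE_DEG = 75.0  # structured-light triangulation dropout angle
_TARGET_OVERLAP = 0.20  # centre of the 15-25% study regime


@dataclass
class HeadFixture:
    """A head surface, one partial scan of it, and the ground truth linking them."""

    full_surface: PointCloud
    scan: PointCloud
    true_transform: RigidTransform  # scan frame -> head frame
    landmark_truth: dict[int, np.ndarray]  # head frame
    scan_landmarks: dict[int, np.ndarray]  # scan frame
    overlap_fraction: float
    direction: Direction
    noise_sigma: float
    seed: int


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _gaussian_bump(dirs: np.ndarray, center: np.ndarray, width_rad: float) -> np.ndarray:
    ang = np.arccos(np.clip(dirs @ center, -1.0, 1.0))
    return np.exp(-((ang / width_rad) ** 2))


class _HeadShape:
    """Radius field r(u) of one seeded head; evaluable at arbitrary directions."""

    def __init__(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.96, 1.04, size=3)
        self.axes = np.array([78.0, 105.0, 88.0]) * jitter  # x half-width, y, z
        self.exponent = 2.5
        # fixed anatomical features: (direction, amplitude mm, width rad)
        feats = [
            ((0.0, -0.12, -1.0), 24.0, 0.16),  # nose ridge
            ((0.0, 0.25, -1.0), 6.0, 0.35),  # brow
            ((-0.38, 0.18, -1.0), -7.0, 0.20),  # eye sockets
            ((0.38, 0.18, -1.0), -7.0, 0.20),
            ((-0.55, -0.05, -0.85), 5.0, 0.30),  # cheekbones
            ((0.55, -0.05, -0.85), 5.0, 0.30),
            ((0.0, -0.75, -0.65), 9.0, 0.30),  # chin
            ((-0.50, -0.55, -0.60), 5.0, 0.35),  # jaw
            ((0.50, -0.55, -0.60), 5.0, 0.35),
        ]
        # seeded low-frequency individual variation, kept off the face so the
        # landmark anatomy stays canonical
        nose_dir = _unit(_LANDMARK_DIRECTIONS[19])
        for _ in range(8):
            d = _unit(rng.normal(size=3))
            if np.arccos(np.clip(d @ nose_dir, -1, 1)) < math.radians(75.0):
                d = _unit(d - 1.5 * nose_dir)  # push the lobe off the face
            feats.append((tuple(d), float(rng.normal(0.0, 2.0)), float(rng.uniform(0.4, 0.8))))
        self.features = [(np.asarray(_unit(d)), a, w) for d, a, w in feats]

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        base = np.sum((np.abs(dirs) / self.axes) ** self.exponent, axis=1) ** (-1.0 / self.exponent)
        r = base.copy()
        for center, amp, width in self.features:
            r += amp * _gaussian_bump(dirs, center, width)
        return r

    def surface(self, dirs: np.ndarray) -> np.ndarray:
        return dirs * self.radius(dirs)[:, None]


def make_head(seed: int, n_points: int = 100_000) -> tuple[PointCloud, dict[int, np.ndarray]]:
    """Deterministic-for-seed head surface + 3D landmark truth (head frame).

    Points quasi-uniformly sample the closed surface (Fibonacci directions
    through the seeded radius field). The landmark-234↔454 facial width is
    guaranteed to fall in the anthropometric 120–160 mm band.
    """
    if n_points < 10_000:
        raise InvalidInputError("make_head requires n_points >= 10000")
    shape = _HeadShape(seed)
    rng = np.random.default_rng(seed + 977)
    dirs = _fibonacci_sphere(n_points)
    # seeded random rotation of the direction lattice: different seeds sample
    # different lattice orientations
    from scipy.spatial.transform import Rotation

    lattice_rot = Rotation.random(random_state=rng).as_matrix()
    # keep the face region sampled identically enough: rotate, radii handle shape
    dirs = dirs @ lattice_rot.T
    pts = shape.surface(dirs)
    landmarks = {
        idx: shape.surface(_unit(d))[0] for idx, d in _LANDMARK_DIRECTIONS.items()
    }
    width = float(np.linalg.norm(landmarks[454] - landmarks[234]))
    if not (120.0 <= width <= 160.0):  # pragma: no cover - guards the generator itself
        raise InvalidInputError(f"generated facial width {width:.1f} mm outside [120, 160]")
    return PointCloud(pts), landmarks


def _hidden_point_removal(points: np.ndarray, viewpoint: np.ndarray, radius_factor: float = 5.0) -> np.ndarray:
    """Katz spherical-flip visibility: indices of points visible from viewpoint."""
    rel = points - viewpoint
    norms = np.linalg.norm(rel, axis=1)
    radius = norms.max() * radius_factor
    flipped = rel + 2.0 * (radius - norms)[:, None] * (rel / norms[:, None])
    hull = ConvexHull(np.vstack([flipped, np.zeros(3)]))
    visible = np.unique(hull.vertices)
    return visible[visible < len(points)]


def _random_rigid_offset(rng: np.random.Generator, max_angle_deg: float = 30.0, max_translation: float = 50.0) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    axis = _unit(rng.normal(size=3))
    angle = math.radians(rng.uniform(0.3 * max_angle_deg, max_angle_deg))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(0.4, 1.0) * max_translation * _unit(rng.normal(size=3))
    return RigidTransform.from_rotation_translation(r, t)


def make_scan(
    head: PointCloud,
    landmarks: Mapping[int, np.ndarray],
    direction: Direction = "center",
    noise_sigma: float = 0.1,
    clutter: bool = True,
    seed: int = 0,
) -> HeadFixture:
    """Simulate one structured-light capture of the head.

    Pipeline: hair-like shell over the non-face scalp (clutter only) →
    hidden-point removal from the scan camera (0/±30° azimuth, 800 mm) →
    torso/clothing slab below the chin (clutter only, sized so the default
    scan→head overlap lands near 20%) → isotropic Gaussian noise → random
    rigid offset (≤ 30°, ≤ 50 mm), recorded as ``true_transform⁻¹``.

    With ``clutter=False`` the noiseless scan is an exact subset of the head
    surface.
    """
    rng = np.random.default_rng(seed + 40_427)
    nose_dir = _unit(_LANDMARK_DIRECTIONS[19])
    pts = head.points
    dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    face_angle = np.arccos(np.clip(dirs @ nose_dir, -1.0, 1.0))

    scene = pts.copy()
    if clutter:
        # hair/cap analogue: smooth outward shell beyond the face cap,
        # invisible to CBCT just like real hair
        t0, t1 = math.radians(_FACE_CAP_START_DEG), math.radians(_FACE_CAP_END_DEG)
        s = np.clip((face_angle - t0) / (t1 - t0), 0.0, 1.0)
        s = s * s * (3.0 - 2.0 * s)  # smoothstep
        thickness = 18.0 + 8.0 * np.sin(3.0 * dirs @ _unit(rng.normal(size=3)))
        scene = scene + (s * thickness)[:, None] * dirs

    azimuth = {"left": -30.0, "center": 0.0, "right": 30.0}[direction]
    az = math.radians(azimuth)
    viewpoint = _SCAN_DISTANCE_MM * np.array([math.sin(az), 0.0, -math.cos(az)])
    visible = _hidden_point_removal(scene, viewpoint)
    # structured-light dropout at grazing incidence: triangulation fails when
    # the surface tilts more than ~75 degrees away from the camera ray
    toward = viewpoint - scene[visible]
    toward /= np.linalg.norm(toward, axis=1, keepdims=True)
    grazing = np.einsum("ni,ni->n", dirs[visible], toward) > math.cos(math.radians(_MAX_INCIDENCE_DEG))
    visible = visible[grazing]
    scan_pts = scene[visible]
    face_visible = int(np.count_nonzero(face_angle[visible] < math.radians(_FACE_CAP_START_DEG)))

    if clutter:
        # torso/clothing slab: sized so face points are ~20% of the scan,
        # the low-overlap regime characteristic of this multimodal pairing
        n_torso = max(int(round(face_visible / _TARGET_OVERLAP)) - len(scan_pts), 0)
        y_top = pts[:, 1].min() - 45.0
        x = rng.uniform(-210.0, 210.0, size=n_torso)
        y = rng.uniform(y_top - 320.0, y_top, size=n_torso)
        z = -55.0 + 0.0009 * x**2 + 6.0 * np.sin(0.03 * x) * np.cos(0.02 * y)
        torso = np.column_stack([x, y, z])
        scan_pts = np.vstack([scan_pts, torso])

    if noise_sigma > 0:
        scan_pts = scan_pts + rng.normal(0.0, noise_sigma, size=scan_pts.shape)

    offset = _random_rigid_offset(rng)
    scan_pts = offset.transform_points(scan_pts)
    true_transform = offset.inverse()

    lm_truth = {int(k): np.asarray(v, dtype=np.float64).copy() for k, v in landmarks.items()}
    scan_landmarks = {k: offset.transform_points(v[None, :])[0] for k, v in lm_truth.items()}

    scan = PointCloud(scan_pts)
    back = true_transform.transform_points(scan_pts)
    tree = cKDTree(pts)
    d, _ = tree.query(back)
    overlap = float(np.count_nonzero(d < 0.5)) / len(scan)

    return HeadFixture(
        full_surface=head,
        scan=scan,
        true_transform=true_transform,
        landmark_truth=lm_truth,
        scan_landmarks=scan_landmarks,
        overlap_fraction=overlap,
        direction=direction,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_fixture(
    seed: int,
    n_points: int = 100_000,
    direction: Direction = "center",
    noise_sigma: float = 0.1,
    clutter: bool = True,
) -> HeadFixture:
    """make_head + make_scan with a single seed."""
    head, landmarks = make_head(seed, n_points)
    return make_scan(head, landmarks, direction=direction, noise_sigma=noise_sigma, clutter=clutter, seed=seed)


class OracleLandmarkProvider:
    """Ground-truth landmark detector for synthetic fixtures.

    The cloud's current rigid pose is recovered on every call from a set of
    widely spread anchor points (exact for rigid motion), and the 3D landmark
    truth is carried along with it — like a model-based face-mesh detector,
    the oracle reports anatomically correct landmarks even where the local
    surface is occluded in the scan. Landmarks are then reported exactly as
    a detector would: projected pixel coordinates plus relative depth (see
    :func:`craniofuse.pose.detector_frame`), with optional Gaussian pixel
    jitter. Detection fails when the face points more than
    ``max_view_angle_deg`` away from the camera.

    Unlike an image-space detector it does not require the landmarks to lie
    inside the rendered frame, so pose normalization can start from framings
    a real detector would reject.
    """

    _N_ANCHORS = 12

    def __init__(
        self,
        cloud: PointCloud,
        landmarks: Mapping[int, np.ndarray],
        jitter_px: float = 0.0,
        seed: int = 0,
        max_view_angle_deg: float = 90.0,
    ) -> None:
        self.landmarks0 = {int(k): np.asarray(v, dtype=np.float64).copy() for k, v in landmarks.items()}
        missing = [k for k in REQUIRED_LANDMARKS if k not in self.landmarks0]
        if missing:
            raise InvalidInputError(f"landmark truth missing indices {missing}")
        step = max(len(cloud) // self._N_ANCHORS, 1)
        self.anchor_indices = np.arange(0, len(cloud), step)[: self._N_ANCHORS]
        self.anchors0 = cloud.points[self.anchor_indices].copy()
        self.jitter_px = float(jitter_px)
        self.seed = int(seed)
        self.max_view_angle_deg = float(max_view_angle_deg)

    def _current_pose(self, view: RenderedView) -> tuple[np.ndarray, np.ndarray]:
        """Rigid (R, t) taking the original cloud to the viewed one."""
        from scipy.spatial.transform import Rotation

        a0 = self.anchors0
        a1 = view.points[self.anchor_indices]
        c0, c1 = a0.mean(axis=0), a1.mean(axis=0)
        rot, _ = Rotation.align_vectors(a1 - c1, a0 - c0)
        r = rot.as_matrix()
        return r, c1 - r @ c0

    def detect(self, view: RenderedView) -> FaceLandmarks:
        r, t = self._current_pose(view)
        pts = {k: r @ p + t for k, p in self.landmarks0.items()}
        nose = pts[NOSE]
        lateral_mean = np.mean([pts[i] for i in LATERAL_LANDMARKS], axis=0)
        forward = _unit(nose - lateral_mean)
        if nose[2] <= 0 or any(p[2] <= 0 for p in pts.values()):
            raise DetectionFailureError("face behind the camera")
        toward_camera = -_unit(nose)
        if forward @ toward_camera < math.cos(math.radians(self.max_view_angle_deg)):
            raise DetectionFailureError("face turned away from the camera")
        cam = view.camera
        raw = {}
        for k, p in pts.items():
            u = cam.focal_length_px * p[0] / p[2] + cam.principal_point[0]
            v = cam.focal_length_px * p[1] / p[2] + cam.principal_point[1]
            raw[k] = np.array([u, v, p[2]])
        if self.jitter_px > 0:
            # deterministic for a fixed view: the jitter stream is keyed on
            # the projected configuration itself
            key = int(abs(raw[NOSE][0] * 97.0 + raw[NOSE][1] * 131.0) * 1e3) % (2**31)
            jrng = np.random.default_rng((self.seed * 2_654_435_761 + key) % (2**31))
            for k in raw:
                raw[k][:2] += jrng.normal(0.0, self.jitter_px, size=2)
        return detector_frame(raw, cam)


def oracle_landmark_provider(
    fixture: HeadFixture,
    which: Literal["scan", "cbct"] = "scan",
    jitter_px: float = 0.0,
    seed: int = 0,
    max_view_angle_deg: float = 90.0,
) -> OracleLandmarkProvider:
    """Oracle provider for either side of a fixture (scan or CBCT head)."""
    if which == "scan":
        return OracleLandmarkProvider(fixture.scan, fixture.scan_landmarks, jitter_px, seed, max_view_angle_deg)
    return OracleLandmarkProvider(fixture.full_surface, fixture.landmark_truth, jitter_px, seed, max_view_angle_deg)
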