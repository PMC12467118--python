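"""ICP: correspondence gating, closed-form solvers, iteration behavior."""

import numpy as np
import pytest
import trimesh.registration
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from craniofuse.exceptions import DegenerateGeometryError, InvalidInputError
from craniofuse.geometry import PointCloud, RigidTransform, compose, rotation_angle_deg
from craniofuse.icp import (
    CorrespondenceSet,
    ICPConfig,
    estimate_normals,
    find_correspondences,
    run_icp,
    solve_point_to_plane,
    solve_point_to_point,
)
from conftest import random_rigid


def brute_force_correspondences(src: np.ndarray, tgt: np.ndarray, threshold: float):
    """O(N²) oracle for nearest-neighbour gating."""
    pairs = []
    for qi, q in enumerate(src):
        d = np.linalg.norm(tgt - q, axis=1)
        pi = int(np.argmin(d))
        if d[pi] < threshold:
            pairs.append((pi, qi, d[pi]))
    return pairs


class TestFindCorrespondences:
    def test_identical_clouds_all_paired_at_zero(self, random_cloud):
        corr = find_correspondences(random_cloud, random_cloud, threshold=1.0)
        assert len(corr) == len(random_cloud)
        assert np.allclose(corr.distances, 0.0)
        assert np.array_equal(corr.target_indices, corr.source_indices)

    def test_shift_beyond_gate_yields_no_pairs(self):
        tgt = PointCloud(np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]]))
        src = PointCloud(tgt.points + [10.0, 0.0, 0.0])
        corr = find_correspondences(src, tgt, threshold=5.0)
        assert len(corr) == 0

    def test_matches_brute_force_oracle(self, rng):
        for threshold in (0.5, 2.0, 10.0):
            src = rng.normal(scale=5.0, size=(120, 3))
            tgt = rng.normal(scale=5.0, size=(150, 3))
            corr = find_correspondences(PointCloud(src), PointCloud(tgt), threshold)
            oracle = brute_force_correspondences(src, tgt, threshold)
            assert sorted(zip(corr.target_indices, corr.source_indices)) == sorted(
                (p, q) for p, q, _ in oracle
            )

    def test_strict_gate_excludes_boundary(self):
        tgt = PointCloud(np.array([[0.0, 0.0, 0.0]]))
        src = PointCloud(np.array([[3.0, 0.0, 0.0]]))
        assert len(find_correspondences(src, tgt, threshold=3.0)) == 0
        assert len(find_correspondences(src, tgt, threshold=3.0 + 1e-9)) == 1


def make_pairs(n: int) -> CorrespondenceSet:
    return CorrespondenceSet(np.arange(n), np.arange(n), np.zeros(n), threshold=np.inf)


class TestSolvePointToPoint:
    def test_identity_for_identical_pairs(self, rng):
        pts = rng.normal(scale=10.0, size=(30, 3))
        t = solve_point_to_point(make_pairs(30), pts, pts)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)

    def test_exact_recovery_of_known_transform(self, rng):
        src = rng.normal(scale=10.0, size=(50, 3))
        truth = random_rigid(rng)
        tgt = truth.transform_points(src)
        est = solve_point_to_point(make_pairs(50), src, tgt)
        assert np.allclose(est.matrix, truth.matrix, atol=1e-9)

    def test_matches_scipy_kabsch_oracle(self, rng):
        for _ in range(30):
            src = rng.normal(scale=10.0, size=(25, 3))
            tgt = rng.normal(scale=10.0, size=(25, 3))
            est = solve_point_to_point(make_pairs(25), src, tgt)
            rot, _ = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
            r = rot.as_matrix()
            t = tgt.mean(0) - r @ src.mean(0)
            assert np.allclose(est.rotation, r, atol=1e-9)
            assert np.allclose(est.translation, t, atol=1e-9)

    def test_noisy_pairs_beat_random_perturbations(self, rng):
        src = rng.normal(scale=10.0, size=(40, 3))
        truth = random_rigid(rng, max_angle_rad=0.5, max_translation=5.0)
        tgt = truth.transform_points(src) + rng.normal(scale=0.2, size=(40, 3))
        est = solve_point_to_point(make_pairs(40), src, tgt)

        def objective(t: RigidTransform) -> float:
            return float(np.sum((tgt - t.transform_points(src)) ** 2))

        base = objective(est)
        for _ in range(200):
            perturb = random_rigid(rng, max_angle_rad=0.05, max_translation=0.5)
            assert objective(compose([perturb, est])) >= base - 1e-9

    def test_too_few_or_collinear_pairs_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            solve_point_to_point(make_pairs(2), np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            solve_point_to_point(make_pairs(10), line, line + [0, 1.0, 0])


def plane_objective(xi, q, p, n):
    r = Rotation.from_rotvec(xi[:3]).as_matrix()
    res = np.einsum("ni,ni->n", p - (q @ r.T + xi[3:]), n)
    return float(np.sum(res**2))


class TestSolvePointToPlane:
    def _target(self, pts, rng):
        normals = rng.normal(size=pts.shape)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return PointCloud(pts, normals=normals)

    def test_zero_residual_gives_identity(self, rng):
        pts = rng.normal(scale=10.0, size=(40, 3))
        t = solve_point_to_plane(make_pairs(40), pts, self._target(pts, rng))
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_planar_target_recovers_normal_offset_only(self, rng):
        # in-plane sliding is unpenalized: only the normal component is fixed
        xy = rng.uniform(-20, 20, size=(60, 2))
        plane = np.column_stack([xy, np.zeros(60)])
        normals = np.tile([0.0, 0.0, 1.0], (60, 1))
        target = PointCloud(plane, normals=normals)
        src = plane + [0.0, 0.0, 2.5]
        t = solve_point_to_plane(make_pairs(60), src, target)
        assert np.isclose(t.translation[2], -2.5, atol=1e-9)

    def test_matches_direct_numerical_minimizer(self, rng):
        # small-displacement instances: the single Gauss-Newton step of the
        # linearized solver must land within 1e-6 of the true optimum
        for _ in range(10):
            q = rng.normal(scale=10.0, size=(50, 3))
            truth = random_rigid(rng, max_angle_rad=0.005, max_translation=0.05)
            p = truth.transform_points(q) + rng.normal(scale=0.005, size=(50, 3))
            target = self._target(p, rng)
            est = solve_point_to_plane(make_pairs(50), q, target)
            ours = plane_objective(
                np.concatenate([Rotation.from_matrix(est.rotation).as_rotvec(), est.translation]),
                q,
                p,
                target.normals,
            )
            opt = minimize(plane_objective, np.zeros(6), args=(q, p, target.normals), method="Powell")
            assert ours <= opt.fun + 1e-6

    def test_requires_normals_and_enough_pairs(self, rng):
        pts = rng.normal(size=(10, 3))
        with pytest.raises(InvalidInputError):
            solve_point_to_plane(make_pairs(10), pts, PointCloud(pts))
        with pytest.raises(DegenerateGeometryError):
            solve_point_to_plane(make_pairs(4), pts[:4], PointCloud(pts[:4], normals=np.tile([0.0, 0.0, 1.0], (4, 1))))

    def test_rank_deficient_directions_stay_at_zero(self, rng):
        # all normals parallel: in-plane translation and z-rotation are
        # unpenalized and must come back as zero motion (minimum norm)
        plane = np.column_stack([rng.uniform(-10, 10, (30, 2)), np.zeros(30)])
        normals = np.tile([0.0, 0.0, 1.0], (30, 1))
        t = solve_point_to_plane(
            make_pairs(30), plane + [0.0, 0.0, 1.0], PointCloud(plane, normals=normals)
        )
        assert np.allclose(t.translation[:2], 0.0, atol=1e-9)
        assert np.isclose(t.translation[2], -1.0, atol=1e-9)


class TestEstimateNormals:
    def test_plane_normals_are_vertical(self, rng):
        pts = np.column_stack([rng.uniform(-10, 10, (300, 2)), np.zeros(300)])
        cloud = estimate_normals(PointCloud(pts), k=10)
        assert np.allclose(np.abs(cloud.normals[:, 2]), 1.0, atol=1e-6)
        assert np.allclose(np.linalg.norm(cloud.normals, axis=1), 1.0, atol=1e-9)

    def test_sphere_normals_point_outward(self, rng):
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        cloud = estimate_normals(PointCloud(50.0 * dirs), k=12)
        assert (np.einsum("ni,ni->n", cloud.normals, dirs) > 0.9).all()


@pytest.fixture(scope="module")
def icp_instance(camera):
    """A downsampled partial-overlap pair with a small known displacement."""
    from craniofuse.synthetic import make_head
    from craniofuse.threshold import voxel_downsample

    head, _ = make_head(13, 20_000)
    target = estimate_normals(voxel_downsample(PointCloud(head.points), 1.5), k=20)
    front = target.points[:, 2] < target.points[:, 2].mean()  # frontal half
    rng = np.random.default_rng(5)
    src_pts = target.points[front] + rng.normal(scale=0.05, size=(front.sum(), 3))
    truth = random_rigid(rng, max_angle_rad=np.radians(4.0), max_translation=3.0)
    source = PointCloud(truth.inverse().transform_points(src_pts))
    return source, target, truth


class TestRunICP:
    def test_identical_clouds_converge_first_iterations(self, random_cloud):
        target = estimate_normals(random_cloud, k=8)
        result = run_icp(target, target, config=ICPConfig(threshold=1.0))
        assert result.converged
        assert result.objective_trace[-1] < 1e-12
        assert np.allclose(result.transform.matrix, np.eye(4), atol=1e-9)

    @pytest.mark.parametrize("variant, threshold", [("point-to-point", 5.0), ("point-to-plane", 3.0)])
    def test_recovers_displacement_on_fixture(self, icp_instance, variant, threshold):
        # the gate must exceed the initial displacement (~4 deg / 3 mm) or the
        # truncated correspondence set biases the estimate — the "threshold
        # too small" failure mode; point-to-point needs the larger gate and
        # more cycles than the 30-iteration default, point-to-plane does not
        source, target, truth = icp_instance
        result = run_icp(
            source, target, config=ICPConfig(threshold=threshold, max_iterations=100, variant=variant)
        )
        err = compose([result.transform, truth.inverse()])
        assert rotation_angle_deg(err) < 0.5
        c = source.points.mean(axis=0)
        assert np.linalg.norm(result.transform.transform_points(c[None])[0] - truth.transform_points(c[None])[0]) < 0.5

    def test_matches_trimesh_reference_implementation(self, icp_instance):
        source, target, truth = icp_instance
        config = ICPConfig(threshold=1e6, max_iterations=60, rel_change_tol=1e-12, variant="point-to-point")
        ours = run_icp(source, target, config=config)
        matrix, _, _ = trimesh.registration.icp(
            source.points,
            target.points,
            threshold=1e-12,
            max_iterations=60,
            scale=False,
            reflection=False,
        )
        reference = RigidTransform(matrix)
        rel = compose([ours.transform, reference.inverse()])
        assert rotation_angle_deg(rel) < 0.1
        c = source.points.mean(axis=0)
        dev = np.linalg.norm(
            ours.transform.transform_points(c[None])[0] - reference.transform_points(c[None])[0]
        )
        assert dev < 0.1

    def test_point_to_point_trace_monotone_with_stable_pairs(self, icp_instance):
        source, target, _ = icp_instance
        result = run_icp(
            source, target, config=ICPConfig(threshold=1e6, max_iterations=40, variant="point-to-point")
        )
        trace = np.array(result.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_invariant_to_source_ordering(self, icp_instance, rng):
        source, target, _ = icp_instance
        perm = rng.permutation(len(source))
        a = run_icp(source, target, config=ICPConfig(threshold=3.0))
        b = run_icp(PointCloud(source.points[perm]), target, config=ICPConfig(threshold=3.0))
        assert np.allclose(a.transform.matrix, b.transform.matrix, atol=1e-9)

    def test_threshold_taxonomy_extremes(self, icp_instance):
        source, target, _ = icp_instance
        huge = find_correspondences(source, target, threshold=1e9)
        assert len(huge) == len(source)
        tiny = find_correspondences(source, target, threshold=1e-9)
        assert len(tiny) == 0
        starved = run_icp(source, target, config=ICPConfig(threshold=1e-9))
        assert starved.failure is not None
        assert starved.iterations_run == 0

    def test_composes_init_transform(self, icp_instance):
        source, target, truth = icp_instance
        result = run_icp(source, target, init=truth, config=ICPConfig(threshold=3.0))
        err = compose([result.transform, truth.inverse()])
        assert rotation_angle_deg(err) < 0.1
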