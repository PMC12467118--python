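import numpy as np
import pytest

from craniofuse.geometry import PointCloud
from craniofuse.projection import CameraModel
from craniofuse.synthetic import make_fixture, make_head


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def small_head():
    """20k-point head + landmark truth; shared across fast tests."""
    return make_head(7, 20_000)


@pytest.fixture(scope="session")
def small_fixture():
    """A complete 30k head/scan fixture with the default study conditions."""
    return make_fixture(7, n_points=30_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rigid(rng: np.random.Generator, max_angle_rad: float = np.pi, max_translation: float = 100.0):
    """A uniformly random rigid transform for property tests."""
    from scipy.spatial.transform import Rotation

    from craniofuse.geometry import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform.from_rotation_translation(r, t)


@pytest.fixture()
def random_cloud(rng) -> PointCloud:
    return PointCloud(rng.normal(scale=40.0, size=(200, 3)))
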