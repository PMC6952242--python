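import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caliper3d import SceneNode, Transform, VolumeImage, attach_volume


def random_quaternion(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def random_transform(rng, *, uniform_scale: bool = False,
                     scale_range=(0.25, 4.0)) -> Transform:
    lo, hi = np.log(scale_range[0]), np.log(scale_range[1])
    if uniform_scale:
        s = np.full(3, np.exp(rng.uniform(lo, hi)))
    else:
        s = np.exp(rng.uniform(lo, hi, size=3))
    return Transform(translation=rng.normal(scale=2.0, size=3),
                     rotation=random_quaternion(rng),
                     scale=s)


def random_rigid(rng) -> Transform:
    return Transform(translation=rng.normal(scale=2.0, size=3),
                     rotation=random_quaternion(rng))


def random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume(rng):
    """A 16^3 volume, 0.5 mm isotropic, with a random orthonormal direction."""
    direction = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
    return VolumeImage(
        voxels=rng.integers(0, 255, size=(16, 16, 16)).astype(np.float32),
        spacing=(0.5, 0.5, 0.5),
        origin=(-3.0, 1.5, 7.0),
        direction=direction,
    )


@pytest.fixture
def scene_with_volume(small_volume):
    root = SceneNode("root")
    vol = attach_volume(root, small_volume)
    return root, vol
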