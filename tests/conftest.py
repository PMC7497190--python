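import numpy as np
import pytest

from scenedefocus import CameraModel, DefocusMap, SceneSpec


@pytest.fixture
def small_camera() -> CameraModel:
    """A low-resolution Kinect-like camera that keeps ray casts cheap."""
    return CameraModel(width=128, height=108)


@pytest.fixture
def flat_scene() -> SceneSpec:
    """Noise-free fronto-parallel plane at the book distance."""
    return SceneSpec(noise_sd=0.0, desk_tilt=0.0, n_frames=1,
                     working_distance=0.30)


def angular_map(values: np.ndarray, half_extent: float = 35.0,
                target_vergence: float = 2.0) -> DefocusMap:
    """Wrap a square array in a DefocusMap on a uniform planar-angle grid."""
    ny, nx = values.shape
    tx = np.linspace(-half_extent, half_extent, nx)
    ty = np.linspace(half_extent, -half_extent, ny)
    return DefocusMap(values=values, theta_x=tx, theta_y=ty,
                      target_vergence=target_vergence)


@pytest.fixture
def uniform_myopic_map() -> DefocusMap:
    """Uniform -1 D map on a 256x256 angular grid covering the 30 deg disc."""
    return angular_map(np.full((256, 256), -1.0))
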