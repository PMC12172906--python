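import numpy as np
import pytest

from lesionsub.core import BinaryMask, ImageVolume
from lesionsub.phantoms import LesionSpec, PhantomConfig, generate_study


def small_affine(spacing=(1.0, 1.0, 3.0), shape=(32, 32, 8)):
    sp = np.asarray(spacing, float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(sp)
    aff[:3, 3] = -sp * (np.asarray(shape, float) - 1) / 2
    return aff


@pytest.fixture
def flat_image():
    shape = (24, 24, 6)
    return ImageVolume(np.full(shape, 100.0), small_affine(shape=shape), "PD")


@pytest.fixture
def ball_mask(flat_image):
    ijk = np.indices(flat_image.shape).reshape(3, -1).T
    world = flat_image.voxel_to_world(ijk)
    inside = (world**2).sum(axis=1) <= 8.0**2
    return BinaryMask(
        inside.reshape(flat_image.shape).astype(np.uint8), flat_image.affine.copy()
    )


@pytest.fixture(scope="session")
def two_visit_study():
    """Small phantom pair with one new and one shrinking lesion and known
    in-plane motion; shared across tests to amortize rendering cost."""
    cfg = PhantomConfig(
        grid_shape=(48, 48, 12),
        n_visits=2,
        lesions=(
            LesionSpec((8.0, 6.0, 0.0), (0.0, 4.0)),
            LesionSpec((-9.0, -6.0, 0.0), (4.5, 3.0)),
        ),
        motion_spec=(((0, 0, 0), (0, 0, 0)), ((0, 0, 0), (2.0, -2.0, 0.0))),
        t1_offset_spec=(((0, 0, 0.8), (1.0, 0.5, 0.0)),) * 2,
        seed=11,
    )
    return generate_study(cfg)
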