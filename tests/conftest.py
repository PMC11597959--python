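import numpy as np
import pytest

from pluckvision.scene_io import BinaryMask, Frame


@pytest.fixture
def small_frame():
    """4x4 frame whose cloud has 3 NaN points (13 finite)."""
    h, w = 4, 4
    image = np.zeros((h, w, 3), dtype=np.uint8)
    cloud = np.zeros((h, w, 3))
    cloud[..., 2] = 0.5
    for r, c in [(0, 0), (1, 2), (3, 3)]:
        cloud[r, c] = np.nan
    return Frame(image=image, cloud=cloud, frame_id="tiny")


def disk_mask(h, w, cv, cu, radius):
    """Boolean disk mask centered at row cv, col cu."""
    vv, uu = np.mgrid[0:h, 0:w]
    return BinaryMask(grid=(uu - cu) ** 2 + (vv - cv) ** 2 <= radius ** 2)


@pytest.fixture
def disk_mask_factory():
    return disk_mask


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rotations():
    rng = np.random.default_rng(20240)
    return [random_rotation(rng) for _ in range(50)]
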