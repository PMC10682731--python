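import numpy as np
import pytest

from aortaflow.flow_field_io import SegmentationMask, VelocityField4D


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_field(data, spacing=(2.5, 2.5, 2.5), dt=40.0, venc=200.0, origin=(0, 0, 0)):
    return VelocityField4D(
        data=np.asarray(data, dtype=float),
        spacing=spacing,
        dt=dt,
        venc=venc,
        origin=np.asarray(origin, dtype=float),
    )


@pytest.fixture
def small_random_field(rng):
    """8^3 grid, 3 frames, random velocities, full mask."""
    data = rng.normal(0, 0.5, size=(8, 8, 8, 3, 3))
    field = make_field(data)
    mask = SegmentationMask(voxels=np.ones((8, 8, 8), dtype=bool))
    return field, mask


@pytest.fixture
def blob_mask(rng):
    """Irregular 8^3 mask (random blob, guaranteed nonempty)."""
    vox = rng.random((8, 8, 8)) < 0.55
    vox[3:5, 3:5, 3:5] = True
    return SegmentationMask(voxels=vox)
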