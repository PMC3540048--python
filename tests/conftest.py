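import numpy as np
import pytest

from phmri.phantom import AcquisitionSpec
from phmri.volume import Volume4D, ras_affine


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def acq():
    """Full-length acquisition on the desk-scale grid."""
    return AcquisitionSpec()


@pytest.fixture
def small_vol(rng):
    """A small 4D volume with random content, 3.5 mm voxels, TR 2.5 s."""
    dims = (8, 8, 6)
    data = 100.0 + rng.normal(size=dims + (40,))
    return Volume4D(data=data, affine=ras_affine((3.5, 3.5, 3.5), dims), tr_seconds=2.5)


def make_volume(data, voxel_mm=(3.5, 3.5, 3.5), tr=2.5, t0=0.0):
    data = np.asarray(data, dtype=float)
    return Volume4D(data=data, affine=ras_affine(voxel_mm, data.shape[:3]), tr_seconds=tr, time_origin_s=t0)
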