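import numpy as np
import pytest

from hippomap import synthetic_data as sd
from hippomap.core_io import LabelVolume


@pytest.fixture(scope="session")
def default_spec():
    return sd.PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom_subject(default_spec):
    """One full-resolution phantom brain with ground truth."""
    return sd.make_phantom_subject(default_spec, "P01", "male")


@pytest.fixture(scope="session")
def phantom_contours(phantom_subject):
    volume, _, _ = phantom_subject
    return sd.slice_to_contours(volume, thickness=0.020, mounting_interval=15, mapping_interval=60)


@pytest.fixture(scope="session")
def coarse_spec():
    """Coarser grid for cohort-level tests where speed matters more than
    volumetric accuracy."""
    return sd.PhantomSpec(grid_shape=(64, 64, 64), voxel_size_mm=0.5, seed=23)


@pytest.fixture(scope="session")
def coarse_cohort(coarse_spec):
    return sd.make_cohort(coarse_spec, n_subjects=6)


@pytest.fixture(scope="session")
def sphere_volume():
    """Analytic oracle: a 5 mm radius sphere label on a 0.1 mm grid."""
    vs, n, r = 0.1, 110, 5.0
    origin = -(n - 1) / 2 * vs
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = origin
    idx = np.indices((n, n, n)).reshape(3, -1).T * vs + origin
    labels = (np.sum(idx**2, axis=1) <= r**2).reshape(n, n, n).astype(np.int16)
    return LabelVolume(labels, affine), r
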