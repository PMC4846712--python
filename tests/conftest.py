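import numpy as np
import pytest

from wmhdrift.core import BinaryMask, ImageVolume
from wmhdrift.phantom import PhantomConfig, generate_subject

SMALL_GRID = (64, 64, 12)


@pytest.fixture(scope="session")
def small_cfg():
    """Small-grid, bias-free configuration for fast unit tests."""
    return PhantomConfig(
        grid_shape=SMALL_GRID,
        n_subjects=3,
        seed=123,
        bias_amplitude=0.0,
        wmh_load_median_ml=6.0,
    )


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    return generate_subject(small_cfg, "subj000", 321)


@pytest.fixture(scope="session")
def biased_cfg():
    return PhantomConfig(
        grid_shape=SMALL_GRID,
        n_subjects=3,
        seed=123,
        bias_amplitude=0.2,
        wmh_load_median_ml=6.0,
    )


@pytest.fixture(scope="session")
def biased_subject(biased_cfg):
    return generate_subject(biased_cfg, "subj000", 321)


@pytest.fixture()
def flat_volume():
    return ImageVolume(np.full((8, 8, 4), 50.0), voxel_dims=(1.0, 1.0, 1.0))


def make_mask(data, voxel_dims=(1.0, 1.0, 1.0), label="ICV"):
    return BinaryMask(data=np.asarray(data, dtype=bool), voxel_dims=voxel_dims, label=label)
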