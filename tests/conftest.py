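import numpy as np
import pytest

from anatcorr.datatypes import Segmentation
from anatcorr.phantom import PhantomConfig, make_null_covariate, make_segmentation, simulate_subjects


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(
        shape=(16, 16, 16), voxel_size=(2.0, 2.0, 2.0), n_organs=3,
        n_subjects=20, noise_sd=1.0, smooth_fwhm=4.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    seg = make_segmentation(small_config)
    cov = make_null_covariate(small_config.n_subjects, 123)
    stack = simulate_subjects(seg, cov, small_config)
    return seg, cov, stack


# --- tiny instance for exhaustive-enumeration cross-checks: 3 subjects -> 6
# permutations, 12 voxels. Values are "generic" (no symmetry), so permutation
# statistics carry no near-ties and exact p agreement is well defined.

TINY_SHAPE = (3, 2, 2)
TINY_COV = np.array([0.31, 1.77, -0.94])


@pytest.fixture(scope="session")
def tiny_instance():
    rng = np.random.default_rng(2024)
    stack = rng.normal(size=(*TINY_SHAPE, 3))
    mask = np.ones(TINY_SHAPE, dtype=bool)
    return stack, TINY_COV.copy(), mask


@pytest.fixture(scope="session")
def tiny_segmentation():
    labels = np.zeros(TINY_SHAPE, dtype=np.int32)
    labels[0] = 1          # 4 voxels
    labels[1:3, :, 0] = 2  # 4 voxels
    labels[1:3, :, 1] = 3  # 4 voxels
    return Segmentation(labels, {1: "organ_a", 2: "organ_b", 3: "organ_c"})
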