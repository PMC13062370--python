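import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lnmcircuit as lc
from lnmcircuit.lnm import NormativeCohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: master seed of the documented default planted study
STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """The default planted synthetic study (documented seed)."""
    return lc.simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def cohort(study):
    return NormativeCohort(study.hc_bold)


@pytest.fixture(scope="session")
def pipeline(study, cohort):
    by = study.lesions_by_group()
    return lc.run_pipeline(by["G1"], by["G3"], cohort)


@pytest.fixture
def toy_grid():
    """Tiny all-in-mask 3 mm grid for unit tests, symmetric about x = 0."""
    def make(shape=(6, 6, 6), voxel=3.0, mask=None):
        affine = np.diag([voxel, voxel, voxel, 1.0])
        for ax in range(3):
            affine[ax, 3] = -(shape[ax] - 1) / 2.0 * voxel
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return lc.VolumeGrid(shape=shape, affine=affine, brain_mask=mask)
    return make
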