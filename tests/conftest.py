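import numpy as np
import pytest

from lag3pet.calibration import (
    default_occupancy_model,
    default_organ_params,
    default_plasma_params,
    refined_tumor_model,
)
from lag3pet.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def plasma4():
    return default_plasma_params(4.0)


@pytest.fixture(scope="session")
def occupancy_model():
    model, _ = default_occupancy_model()
    return model


@pytest.fixture(scope="session")
def spleen_params():
    return default_organ_params()["spleen"]


@pytest.fixture(scope="session")
def tumor_model():
    return refined_tumor_model()


@pytest.fixture(scope="session")
def default_cohort(tumor_model):
    return generate_cohort(CohortConfig(seed=11), tumor_model=tumor_model)


@pytest.fixture(scope="session")
def noisefree_cohort(tumor_model):
    cfg = CohortConfig(seed=11, noise_cv=0.0)
    return generate_cohort(cfg, tumor_model=tumor_model)


@pytest.fixture
def rng():
    return np.random.default_rng(20230302)
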