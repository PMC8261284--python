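import numpy as np
import pytest

from viscereb.synthcohort import (
    AcquisitionSpec,
    GeneratorConfig,
    make_cohort,
    make_subject,
    subject_seed,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_acq():
    """Short scan / few voxels: cheap cohorts for structural tests."""
    return AcquisitionSpec(n_volumes=80, n_drop=10, voxels_per_roi=10)


@pytest.fixture(scope="session")
def small_config(small_acq):
    return GeneratorConfig(acquisition=small_acq)


@pytest.fixture(scope="session")
def default_patient():
    """One default-size patient subject (full 180-volume acquisition)."""
    return make_subject("patient", subject_seed(7, 0), GeneratorConfig())


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return make_cohort(n_patients=5, n_controls=3, config=small_config,
                       master_seed=11)
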