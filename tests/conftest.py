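import numpy as np
import pytest

from fentanyltwin import (
    SolverSettings,
    base_case_patient,
    build_patient,
    run_conventional,
    run_precalibrated,
)

AGES = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@pytest.fixture(scope="session")
def base_patient():
    """Age-20 reference patient with the tabulated 320 um equivalent dermis."""
    return base_case_patient()


@pytest.fixture(scope="session")
def conventional_result(base_patient):
    """Three 72-h patches over 216 h for the reference patient."""
    return run_conventional(base_patient)


@pytest.fixture(scope="session")
def single_patch_result(base_patient):
    """One 72-h patch, horizon 72 h (the first-patch analysis window)."""
    return run_conventional(base_patient, n_patches=1, wear_h=72.0, horizon_h=72.0)


@pytest.fixture(scope="session")
def precalibrated_result(base_patient):
    return run_precalibrated(base_patient)


@pytest.fixture(scope="session")
def age_sweep_results():
    """Conventional therapy across the studied age range with the age
    relations driving the skin geometry."""
    out = {}
    for age in AGES:
        out[age] = run_conventional(build_patient(age))
    return out
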