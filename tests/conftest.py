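import warnings

import numpy as np
import pytest

import radstab as rs


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*expected cell count.*")
        warnings.filterwarnings("ignore", message=".*single gray level.*")
        yield


@pytest.fixture(scope="session")
def planted_cohort():
    """One planted survival cohort (clean stable predictors + noisy proxies)."""
    cohort, truth = rs.gen_survival_cohort(rs.planted_survival_spec(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no survival signal (all hazard betas zero)."""
    cohort, truth = rs.gen_survival_cohort(rs.planted_survival_spec(seed=12, null_signal=True))
    return cohort, truth


@pytest.fixture(scope="session")
def toy_cox_data():
    """4-patient toy: times 1..4, all events, interleaved binary covariate
    (a separating covariate would have a monotone partial likelihood)."""
    return np.array([1.0, 0.0, 1.0, 0.0]), np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1])
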