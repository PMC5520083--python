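import numpy as np
import pytest

from survgwas import Scenario, calibrate_params, sample_case_cohort, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20170503)


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-subject cohort with a real genotype effect, for estimator checks."""
    scenario = Scenario(
        design="cohort",
        n_cohort=500,
        raf=0.30,
        hr=1.5,
        incidence=0.15,
        censoring="random",
        seed=42,
    )
    params = calibrate_params(scenario)
    return simulate_cohort(scenario, params, np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_case_cohort():
    """A case-cohort draw (500-subject initial cohort, 30% subcohort)."""
    scenario = Scenario(
        design="case_cohort",
        n_cohort=500,
        raf=0.30,
        hr=1.5,
        incidence=0.15,
        censoring="random",
        sampling_fraction=0.30,
        seed=43,
    )
    params = calibrate_params(scenario)
    cohort = simulate_cohort(scenario, params, np.random.default_rng(43))
    return sample_case_cohort(cohort, 0.30, np.random.default_rng(44))
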