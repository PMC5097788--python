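import numpy as np
import pytest
from hypothesis import settings

from htebayes import (CovariateSpec, build_subgroup_frame,
                      simulate_summary_data)

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def trial_frame():
    """Gender x age x ejection-fraction frame (2 x 2 x 3 = 12 subgroups).

    First declared level is the reference: female, age <= 65, high
    ejection fraction.
    """
    return build_subgroup_frame([
        CovariateSpec("gender", ["female", "male"]),
        CovariateSpec("age", ["le65", "gt65"]),
        CovariateSpec("ejection_fraction", ["high", "medium", "low"]),
    ])


@pytest.fixture(scope="session")
def two_by_two_frame():
    return build_subgroup_frame([
        CovariateSpec("gender", ["male", "female"]),
        CovariateSpec("age", ["young", "old"]),
    ])


@pytest.fixture(scope="session")
def shrinkage_data(trial_frame):
    """A G=12 summary fixture drawn from the two-stage generative model:
    overall effect -0.3, between-subgroup sd 0.25, standard errors
    spanning 0.1-0.4 (mimicking unequal subgroup sizes)."""
    se = np.linspace(0.1, 0.4, trial_frame.n_subgroups)
    truth, data = simulate_summary_data(
        tau=-0.3, omega=0.25, se_profile=se, frame=trial_frame, seed=20160920)
    return truth, data
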