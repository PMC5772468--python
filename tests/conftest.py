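import numpy as np
import pytest

import circabold as cb


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject cohort with behavioural and sleep records (no BOLD)."""
    cfg = cb.CohortConfig(include=("kss", "pvt", "hypno", "eeg"),
                          shape=(12, 14, 12), eeg_n_subjects=5)
    return cb.simulate_cohort(5, cfg, seed=42)


@pytest.fixture(scope="session")
def default_params():
    return cb.SubjectParams(subject_id="sub-00")


@pytest.fixture(scope="session")
def sd_sched():
    return cb.sd_schedule()


@pytest.fixture(scope="session")
def np_sched():
    return cb.np_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
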