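import numpy as np
import pytest

import socialrl as s


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_schedule():
    return s.build_schedule(s.TaskConfig(), np.random.default_rng(11))


@pytest.fixture(scope="session")
def simulated_session(default_schedule):
    """One session simulated from mid-range population parameters."""
    rng = np.random.default_rng(12)
    dem = s.simulate_demonstrator(default_schedule, rng=rng)
    params = s.SocialRLParams(
        beta_p=2.2, alpha_p=0.58, beta_s=1.83, alpha_s=0.6, kappa=0.13, alpha_o=0.46
    )
    return dem, params, s.simulate_participant(default_schedule, dem, params, rng)


@pytest.fixture(scope="session")
def fitted_cohort():
    """A small single-sample cohort with per-subject MAP fits (shared across
    tests because fitting dominates runtime)."""
    rng = np.random.default_rng(2024)
    cohort = s.generate_cohort(s.CohortSpec(n_subjects=40, n_samples=1), rng)
    fits = s.fit_cohort(cohort.sessions)
    return cohort, fits
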