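import numpy as np
import pytest

from calicohort import CleaningParams, clean_cohort, default_config, generate_cohort


def make_clean_cohort(n, seed=0, nonlinear=True, pathologies=False, tail=0.0):
    """Generate-and-clean convenience used across the suite.

    With ``pathologies=False`` and ``tail=0`` the funnel is the identity,
    so the clean cohort has exactly ``n`` participants.
    """
    raw = generate_cohort(default_config(n, seed=seed, nonlinear=nonlinear,
                                         pathologies=pathologies))
    clean, report = clean_cohort(raw, CleaningParams(tail=tail))
    return clean, report


@pytest.fixture(scope="session")
def small_cohort():
    """4,000-participant nonlinear-world clean cohort, no pathologies."""
    clean, _ = make_clean_cohort(4000, seed=101)
    return clean


@pytest.fixture(scope="session")
def raw_cohort():
    """3,000-participant raw cohort with all default pathologies."""
    return generate_cohort(default_config(3000, seed=202))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
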