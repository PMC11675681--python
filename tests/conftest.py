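import numpy as np
import pytest

from hrasleep.features import cohort_segment_table
from hrasleep.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused across test modules."""
    cfg = CohortConfig(n_subjects=6, recording_hours=2.0)
    return generate_cohort(cfg, seed=42), cfg


@pytest.fixture(scope="session")
def small_table(small_cohort):
    cohort, _ = small_cohort
    return cohort_segment_table(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rr(rng, n, base=900.0, sd=40.0, integer=False):
    """Random RR series; optionally integer-valued (creates ties/neutral runs)."""
    x = base + rng.normal(0.0, sd, size=n)
    if integer:
        x = np.round(x / 10.0) * 10.0
    return x
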