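import numpy as np
import pytest

from vitalsid.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient cohort with full-length segments (fast to generate)."""
    cohort, manifest = generate_cohort(
        CohortSpec(n_patients=3, separation=1.5, master_seed=7)
    )
    return cohort, manifest


@pytest.fixture(scope="session")
def full_cohort():
    """Ten-patient cohort with full-length segments 04 and 07."""
    cohort, manifest = generate_cohort(
        CohortSpec(n_patients=10, separation=1.5, master_seed=11)
    )
    return cohort, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
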