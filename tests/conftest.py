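import numpy as np
import pytest

from memoaffect import preprocess, synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Two strongly separable synthetic subjects (shared across tests)."""
    protocol = synthgen.ProtocolConfig(n_subjects=2)
    signatures = synthgen.default_signatures(effect_size=3.0)
    return synthgen.generate_cohort(7, protocol, signatures)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    """Z-scored broadband segments from the two-subject cohort."""
    return preprocess.sessions_to_segments(small_cohort)
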