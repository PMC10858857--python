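import numpy as np
import pytest

from melstage import synthetic
from melstage.staging import Hypnogram


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic subjects x 30 epochs, UCDDB-like 128/64 Hz rates."""
    return synthetic.make_dataset(n_subjects=4, epochs_per_subject=30, seed=2024)


@pytest.fixture()
def flat_hypnogram():
    def make(stages, subject_id="T01"):
        return Hypnogram(stages=list(stages), subject_id=subject_id)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
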