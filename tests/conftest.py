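import logging

import numpy as np
import pytest
from hypothesis import settings

from copreserve import SimProfile, simulate_cohort
from copreserve.preprocess import preprocess_cohort
from copreserve.template import build_template

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# the contiguous-outlier diagnostic fires constantly on strongly drifting
# synthetic patients; keep test output readable
logging.getLogger("copreserve.preprocess").setLevel(logging.ERROR)
logging.getLogger("copreserve.select").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """24 subjects, one posture, short trials: fast but fully structured."""
    profile = SimProfile(
        n_controls=12, n_patients=12, postures=("ST",), trials_per_posture=2,
        T=200, reserve="uniform", seed=11,
    )
    return simulate_cohort(profile)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    return preprocess_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_template(small_cohort, small_preprocessed):
    return build_template(small_cohort, "ST", preprocessed=small_preprocessed)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
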