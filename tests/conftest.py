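"""Shared fixtures.

The heavy session fixtures run full- or near-full-scale simulations once and
are shared between the unit suite and the acceptance suite.
"""

import numpy as np
import pytest

from sornlab.params import SornParams
from sornlab.tasks import run_inference, run_random_letters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return SornParams(n_exc=40, n_input=4, seed=0)


@pytest.fixture(scope="session")
def random_letters_result():
    """Full-scale random-letters experiment (basic network statistics)."""
    return run_random_letters(seed=101)


@pytest.fixture(scope="session")
def inference_result():
    """One full-scale inference run with ambiguous testing (prior 0.33)."""
    return run_inference(seed=202, prior_a=0.33)


@pytest.fixture(scope="session")
def inference_unambiguous_pair():
    """Unambiguous-test inference runs at priors 0.1/0.9 for the
    trial-aligned variability analyses (several realizations)."""
    return [
        run_inference(seed=303 + k, prior_a=0.1, test_mode="unambiguous",
                      keep_recordings=False)
        for k in range(10)
    ]
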