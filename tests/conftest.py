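import numpy as np
import pytest

import gutnk


@pytest.fixture(scope="session")
def default_cohort():
    """The default-size cohort (28 HD / 27 pre / 22 post), seed 0."""
    return gutnk.generate_cohort(gutnk.default_config(seed=0))


@pytest.fixture(scope="session")
def scored_default_cohort(default_cohort):
    return gutnk.score_cohort(default_cohort)


@pytest.fixture(scope="session")
def medium_cohort():
    """100 subjects per group for distributional checks."""
    return gutnk.generate_cohort(
        gutnk.default_config(seed=7, n_hd=100, n_pre=100, n_post=100))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
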