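import numpy as np
import pytest

import svrlsm


@pytest.fixture(scope="session")
def toy_atlas():
    return svrlsm.generate_toy_atlas((20, 24, 20), 8, seed=1)


@pytest.fixture(scope="session")
def small_cohort(toy_atlas):
    """40-subject null cohort on the toy grid (no planted effects)."""
    spec = svrlsm.toy_spec(n_subjects=40, seed=3)
    return svrlsm.generate_cohort(spec, toy_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
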