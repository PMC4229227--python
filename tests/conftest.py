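import numpy as np
import pytest

from wmiquant import synthetic as syn


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the published group means (seed fixed)."""
    return syn.simulate_cohort(syn.default_cohort_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
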