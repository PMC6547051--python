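import numpy as np
import pytest

from betalearn.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """6+6 subjects with traces; shared across tests that only read it."""
    spec = CohortSpec(n_young=6, n_elderly=6, seed=11)
    return generate_cohort(spec, tracking="traces", eeg="none")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
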