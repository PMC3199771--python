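import numpy as np
import pytest

import sisterrange as sr


@pytest.fixture(scope="session")
def toy():
    """Deterministic hand-built 8-species dataset (4 sister pairs)."""
    return sr.make_fixture()


@pytest.fixture(scope="session")
def synth_small():
    """A 60-tip synthetic dataset shared by tests that only need structure."""
    return sr.generate_dataset(sr.SynthConfig(seed=7, n_tips=60))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
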