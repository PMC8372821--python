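import numpy as np
import pytest

from lateromics.phantom import PhantomSpec, make_cohort, make_toy_fixtures


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixtures()


@pytest.fixture(scope="session")
def small_phantom_subject():
    """One patient + one control on a small grid, shared across tests."""
    spec = PhantomSpec(n_patients=1, n_controls=1, shape=(40, 40, 28), seed=42)
    return make_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
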