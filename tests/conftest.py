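import numpy as np
import pytest

from erv_charter.synthetic_data import make_reference, simulate_genome


@pytest.fixture(scope="session")
def toy_reference():
    """2 kb synthetic consensus with canonical region proportions."""
    return make_reference(7, 2000)


@pytest.fixture(scope="session")
def full_reference():
    """Full-scale (8,608 nt) synthetic consensus with the default layout."""
    return make_reference(11, 8608)


@pytest.fixture(scope="session")
def simulation():
    """One seeded synthetic genome with planted proviruses and solo LTRs."""
    return simulate_genome(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
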