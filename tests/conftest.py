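import pytest
from hypothesis import settings

from allelecut.synthetic_data import SimulationConfig, make_target

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def target():
    """A plain amplicon target with the diagnostic SNP 7 nt from the PAM."""
    return make_target(seed=11)


@pytest.fixture
def loxp_target():
    return make_target(seed=12, with_loxp=True)


@pytest.fixture
def junction_target():
    return make_target(seed=13, with_junction=True)


@pytest.fixture
def small_config():
    """Error-free small run for exact-recovery checks."""
    return SimulationConfig(seed=5, n_read_pairs=300, error_rate=0.0)
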