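import pytest

from tosca.simulate import SimConfig, simulate_variant_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample cohort shared across read-only tests."""
    return simulate_variant_cohort(SimConfig(n_cases=20, n_controls=10, seed=11))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cases=20, n_controls=10, seed=11)
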