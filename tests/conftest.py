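import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from dimerpop.species_io import Role
from dimerpop.synthetic_data import GeneratorConfig, make_dimer_system, make_species


@pytest.fixture()
def config():
    return GeneratorConfig(seed=7)


@pytest.fixture()
def dimer_record(config):
    return make_species(config, Role.PROTON_BOUND_DIMER, "C12H17O2", label="d1",
                        protonation_site=2)


@pytest.fixture()
def two_state():
    """Equal-q two-state system with a 1.0 kcal/mol gap."""
    cfg = GeneratorConfig(seed=3, dH_gaps=(0.0, 1.0))
    return make_dimer_system(cfg)


@pytest.fixture()
def three_state():
    """Equal-q three-state system mimicking a 0.4/1.2 kcal/mol spread."""
    cfg = GeneratorConfig(seed=5, dH_gaps=(0.0, 0.4, 1.2))
    return make_dimer_system(cfg)
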