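import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def palmitate_formula():
    from pericell import MolecularFormula

    return MolecularFormula.parse("C17H34O2")


@pytest.fixture(scope="session")
def palmitate_natural(palmitate_formula):
    from pericell import natural_pattern

    return natural_pattern(palmitate_formula)
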