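import pytest
from hypothesis import HealthCheck, settings

from domgi.io import DomainAssignment, InteractionCatalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_assignments() -> DomainAssignment:
    """Three single-domain proteins: A carries d1, B and C carry d2."""
    return DomainAssignment(
        {
            "A": frozenset({"d1"}),
            "B": frozenset({"d2"}),
            "C": frozenset({"d2"}),
        }
    )


@pytest.fixture
def toy_catalog() -> InteractionCatalog:
    """A single observed SLGI between A and B."""
    return InteractionCatalog(frozenset({("A", "B")}))
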