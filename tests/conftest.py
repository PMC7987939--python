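import pytest

from sbsites.constructs import default_registry
from sbsites.seqcore import ReferenceGenome


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def native_construct(registry):
    return registry.get("pYT11")


@pytest.fixture(scope="session")
def mutant_construct(registry):
    return registry.get("pYT23")


@pytest.fixture
def toy_genome():
    return ReferenceGenome({"c1": "ACGTAC", "c2": "CCCTAGGG"})
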