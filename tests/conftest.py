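import pytest

from degradomap import ProteinRecord
from degradomap.datasets import call_evidence_sites, scaffold_substrate


@pytest.fixture(scope="session")
def scaffold():
    return scaffold_substrate()


@pytest.fixture(scope="session")
def adamts4_caller():
    """Site caller fitted on the bundled ADAMTS4/COMP evidence table."""
    return call_evidence_sites("adamts4")


@pytest.fixture(scope="session")
def adamts1_caller():
    """Site caller fitted on the bundled ADAMTS1/COMP evidence table."""
    return call_evidence_sites("adamts1")


@pytest.fixture
def toy_protein():
    return ProteinRecord("TOY", "AKNTVSRGGWMKPLDE")
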