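import pytest

from chemxref import MockKeyBackend, RDKitBackend, Registry
from chemxref.synthetic import diazepam_fixture, load_history


@pytest.fixture
def mock_backend():
    return MockKeyBackend()


@pytest.fixture(scope="session")
def real_backend():
    return RDKitBackend()


@pytest.fixture
def registry():
    with Registry() as reg:
        yield reg


@pytest.fixture
def diazepam_registry(real_backend):
    """A fresh store with the three-source diazepam scenario loaded."""
    with Registry() as reg:
        load_history(reg, diazepam_fixture(), real_backend)
        yield reg
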