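import pytest

import ccfo
from ccfo.extraction import ExtractionConfig
from ccfo.scoring import load_rules


@pytest.fixture(scope="session")
def ont():
    """In-paper fixture: every concept printed with a CCFOID in the source."""
    return ccfo.load_in_paper_ontology()


@pytest.fixture(scope="session")
def full_ont():
    """Synthetic stand-in padded to the published ontology shape."""
    return ccfo.build_full_synthetic_ontology()


@pytest.fixture(scope="session")
def cfg():
    return ExtractionConfig.load()


@pytest.fixture(scope="session")
def rules():
    return load_rules()
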