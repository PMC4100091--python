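import pytest

from photoxl.chem import default_context
from photoxl.study import study_database, study_peptides, study_protein


@pytest.fixture(scope="session")
def ctx():
    return default_context()


@pytest.fixture(scope="session")
def protein():
    return study_protein()


@pytest.fixture(scope="session")
def peptides():
    return study_peptides()


@pytest.fixture(scope="session")
def db():
    return study_database()
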