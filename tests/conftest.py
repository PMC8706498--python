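import pytest

from hybdiag.seq_io import PARENTAL_A, PARENTAL_B, QUERY
from hybdiag.synthetic_data import (
    COI_PREFIXES,
    paper_full_fixture,
    table2_coi_fixture,
)


@pytest.fixture(scope="session")
def coi_fixture():
    """(alignment, metadata) of the packaged 30-sample mitochondrial fixture."""
    return table2_coi_fixture()


@pytest.fixture(scope="session")
def coi_aln(coi_fixture):
    return coi_fixture[0]


@pytest.fixture(scope="session")
def coi_meta(coi_fixture):
    return coi_fixture[1]


@pytest.fixture(scope="session")
def coi_prefixes():
    return COI_PREFIXES


@pytest.fixture(scope="session")
def full_fixture():
    """(alignments, metadata, clone_sets) of the four-locus packaged fixture."""
    return paper_full_fixture()


@pytest.fixture
def groups():
    return PARENTAL_A, PARENTAL_B, QUERY
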