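import pytest

from tcrumi.extract import MoleculeRecord
from tcrumi.germline import toy_germline


@pytest.fixture(scope="session")
def trb():
    return toy_germline("TRB")


@pytest.fixture(scope="session")
def tra():
    return toy_germline("TRA")


def make_record(
    umi: str = "AAAACCCCGGGG",
    v_id: str = "TBV1",
    j_id: str = "TBJ1",
    cdr3: str = "TGTGCCAGCGGGGACTTT",
    j_tail: str = "GGCGTAGGCCCT",
    reads: int = 2,
) -> MoleculeRecord:
    """Convenience molecule record; junction = cdr3 + J tail."""
    return MoleculeRecord(umi, v_id, j_id, cdr3 + j_tail, cdr3, reads)


@pytest.fixture
def record_factory():
    return make_record
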