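import pytest

from genesig.genelists import GeneID, GeneList, GeneRecord, IDMappingTable
from genesig.tumor_score import ScoringEntry, ScoringTable


def make_list(name, ids, direction="unspecified"):
    return GeneList.from_records(
        name, (GeneRecord(GeneID(str(i)), direction) for i in ids)
    )


@pytest.fixture
def toy_mapping():
    return IDMappingTable.from_pairs(
        [("pA", "1"), ("pA", "2"), ("pB", "3"), ("pC", "3"), ("pD", "4")]
    )


@pytest.fixture
def toy_table():
    """One category with ranks {1, 2, 3} (C = 1/3) and one with {1, 4}."""
    return ScoringTable(
        [
            ScoringEntry("gA", "X", +1, 1),
            ScoringEntry("gB", "X", -1, 2),
            ScoringEntry("gC", "X", +1, 3),
            ScoringEntry("gD", "Y", +1, 1),
            ScoringEntry("gE", "Y", -1, 4),
        ]
    )


@pytest.fixture
def split_fixture_list():
    """539-record list split 301 up / 238 down, mimicking the printed
    Table-2-style totals for the biopsy list."""
    records = [GeneRecord(GeneID(f"u{i}"), "up") for i in range(301)]
    records += [GeneRecord(GeneID(f"d{i}"), "down") for i in range(238)]
    return GeneList.from_records("list_A_like", records)
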