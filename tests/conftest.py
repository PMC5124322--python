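import pandas as pd
import pytest

from respiroscreen.tables_io import ColonyTable, GeneMap


@pytest.fixture
def small_plate() -> ColonyTable:
    """One plate, four colonies, sizes [2, 4, 4, 6] (median 4)."""
    return ColonyTable.from_frame(pd.DataFrame({
        "plate_id": "p1", "medium": "glucose",
        "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
        "strain_id": ["a", "b", "c", "d"],
        "size": [2.0, 4.0, 4.0, 6.0],
    }))


@pytest.fixture
def tiny_gene_map() -> GeneMap:
    """Two chromosomes; chr1 carries a coding/ncRNA alternation."""
    rows = []
    for i in range(1, 7):
        rows.append((f"c1g{i}", "chr1", 1000 * i, 1000 * i + 500, "+",
                     "ncRNA" if i % 3 == 0 else "coding"))
    for i in range(1, 4):
        rows.append((f"c2g{i}", "chr2", 1000 * i, 1000 * i + 500, "-", "coding"))
    return GeneMap.from_frame(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]))
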