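import numpy as np
import pandas as pd
import pytest

from urbanmicro.data import AbundanceTable, SampleMetadata


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 OTUs (2 bacterial, 1 viral) x 2 samples."""
    lineages = {
        "otuA": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                 "Enterobacterales", "Enterobacteriaceae", "Escherichia", "coli"),
        "otuB": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                 "Enterobacterales", "Enterobacteriaceae", "Klebsiella", "pneumoniae"),
        "otuV": ("Viruses", "Uroviricota", "Caudoviricetes",
                 "unclassified", "unclassified", "unclassified", "unclassified"),
    }
    counts = np.array([[5, 0], [2, 1], [0, 9]])
    return AbundanceTable(["otuA", "otuB", "otuV"], lineages, counts, ["s1", "s2"])


@pytest.fixture
def two_group_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "city": ["NYC", "NYC", "TOK", "TOK"],
            "year": ["2016"] * 4,
            "total_reads": [100, 120, 90, 110],
        },
        index=pd.Index([f"s{i}" for i in range(4)], name="sample_id"),
    )
    return SampleMetadata(frame)


def make_table(counts: np.ndarray, kingdom: str = "Bacteria") -> AbundanceTable:
    """Helper: table with generic ids/lineages around a given count matrix."""
    counts = np.asarray(counts)
    otus = [f"otu{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    lineages = {o: (kingdom,) + ("unclassified",) * 6 for o in otus}
    return AbundanceTable(otus, lineages, counts, samples)
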