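import numpy as np
import pandas as pd
import pytest

import picosize as ps
from picosize.sm import SAMPLE_LEVELS


@pytest.fixture(scope="session")
def default_truth():
    return ps.default_community()

@pytest.fixture(scope="session")
def separated_truth():
    return ps.well_separated_community()


@pytest.fixture(scope="session")
def simulated_dataset(default_truth):
    """A moderate full survey (all depths, contaminants included)."""
    truth = ps.with_contaminants(default_truth)
    otu, tax, captures = ps.simulate_dataset(
        truth, n_cells=50_000, read_depth=20_000, seed=11
    )
    return truth, otu, tax, captures


def make_otu_table(counts: dict[str, dict[tuple, int]]) -> pd.DataFrame:
    """Build an OTU table from {otu: {(depth, fraction, marker): count}}."""
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=SAMPLE_LEVELS)
    table.index.name = "otu_id"
    return table


@pytest.fixture()
def toy_filter_case():
    """Six-OTU table whose survivors were enumerated by hand.

    One marker, grand total exactly 100 000 reads, so the 0.005% rule
    removes OTUs with fewer than 5 reads.  Hand application of the three
    rules: A kept; B removed (4 < 5 reads); C kept (exactly 5 reads, not
    below threshold); D removed (confidence 0.5); E removed (fungal);
    F removed (unannotated).
    """
    s = lambda n: {(5, "0.2-0.6", "16S"): n}
    table = make_otu_table(
        {"A": s(60000), "B": s(4), "C": s(5), "D": s(20000),
         "E": s(19891), "F": s(100)}
    )
    tax = pd.DataFrame(
        {
            "lineage": [
                "d__Bacteria;p__Cyanobacteria;g__Prochlorococcus",
                "d__Bacteria;p__Cyanobacteria;g__Synechococcus",
                "d__Bacteria;p__Cyanobacteria;g__Synechococcus",
                "d__Bacteria;p__Cyanobacteria;g__Prochlorococcus",
                "d__Eukaryota;p__Fungi;g__Metschnikowia",
                "",
            ],
            "confidence": [0.99, 0.99, 0.99, 0.5, 0.99, 0.0],
            "group": ["Prochlorococcus", "Synechococcus", "Synechococcus",
                      "Prochlorococcus", "excluded", "excluded"],
            "marker": ["16S"] * 6,
        },
        index=pd.Index(list("ABCDEF"), name="otu_id"),
    )
    return table, tax, {"A", "C"}
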