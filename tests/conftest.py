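import numpy as np
import pandas as pd
import pytest

from viromenet import AbundanceMatrix, CorrelationNetwork, HostTaxonomyTable


@pytest.fixture
def host_table() -> HostTaxonomyTable:
    """Six reference genomes over two phyla / three genera."""
    rows = {
        "ref1": ["Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
                 "Prochloraceae", "Prochlorococcus", None],
        "ref2": ["Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
                 "Prochloraceae", "Prochlorococcus", None],
        "ref3": ["Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales",
                 "Synechoccaceae", "Synechococcus", None],
        "ref4": ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales",
                 "Pelagibacteraceae", "Pelagibacter", None],
        "ref5": ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales",
                 "Pelagibacteraceae", "Pelagibacter", None],
        "ref6": ["Bacteria", "Proteobacteria", None, None, None, None, None],
    }
    cols = ["domain", "phylum", "class", "order", "family", "genus", "species"]
    return HostTaxonomyTable(pd.DataFrame(rows, index=cols).T)


def make_network(ids, entries) -> CorrelationNetwork:
    """Build a CorrelationNetwork from {(a, b): rho} (zeros elsewhere)."""
    rho = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    np.fill_diagonal(rho.values, 1.0)
    for (a, b), v in entries.items():
        rho.loc[a, b] = rho.loc[b, a] = v
    return CorrelationNetwork(rho)


@pytest.fixture
def counts_matrix() -> AbundanceMatrix:
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 200, size=(6, 30)).astype(float)
    return AbundanceMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(6)],
                     columns=[f"s{j}" for j in range(30)]),
        mode="counts",
    )
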