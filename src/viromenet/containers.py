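"""Core data containers shared across the toolkit.

Matrices are genomes x samples (rows are genomes) throughout the library
API; estimator classes that follow the scikit-learn convention transpose
to samples x features at their boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("viromenet")

COUNTS = "counts"
RELATIVE = "relative"


@dataclass
class AbundanceMatrix:
    """Genome x sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative values, index = genome ids, columns = sample ids.
    mode : {"counts", "relative"}
        Whether values are (possibly fractional) read counts or per-sample
        relative abundances. In relative mode every non-empty sample column
        sums to 1.
    """

    data: pd.DataFrame
    mode: str = COUNTS

    def __post_init__(self) -> None:
        if self.mode not in (COUNTS, RELATIVE):
            raise ValueError(f"unknown mode {self.mode!r}; expected 'counts' or 'relative'")
        if not self.data.index.is_unique:
            raise ValueError("genome ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path, mode: str = COUNTS) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, mode=mode)


@dataclass
class CorrelationNetwork:
    """Symmetric SparCC correlation matrix over genomes.

    ``rho`` has unit diagonal and entries in [-1, 1].
    """

    rho: pd.DataFrame
    n_inference: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        if r.shape[0] != r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.rho.index)

    def to_graph(self, min_abs: float = 0.0):
        """Export edges with |rho| >= min_abs as a networkx graph."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genome_ids)
        r = self.rho.to_numpy()
        ids = self.genome_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if abs(r[i, j]) >= min_abs:
                    g.add_edge(ids[i], ids[j], rho=float(r[i, j]))
        return g

    def to_long_tsv(self, path) -> None:
        ids = self.genome_ids
        r = self.rho.to_numpy()
        rows = [
            (ids[i], ids[j], r[i, j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        pd.DataFrame(rows, columns=["genome_a", "genome_b", "rho"]).to_csv(
            path, sep="\t", index=False
        )

    def to_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path) -> "CorrelationNetwork":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class HostTaxonomyTable:
    """Mapping from genome id to a ranked host lineage.

    Lineages are stored as a DataFrame with one column per rank
    (domain .. species); absent ranks are NaN/empty and must form a
    contiguous suffix (a lineage never skips a rank).
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.lineages.index.is_unique:
            raise ValueError("genome ids must be unique in the host taxonomy table")
        missing = [r for r in RANKS if r not in self.lineages.columns]
        for r in missing:
            self.lineages[r] = np.nan
        self.lineages = self.lineages[RANKS]
        present = self.lineages.notna() & (self.lineages != "")
        arr = present.to_numpy()
        # present ranks must be a prefix chain from domain downward
        bad = (~arr[:, :-1] & arr[:, 1:]).any(axis=1)
        if bad.any():
            offenders = list(self.lineages.index[bad][:5])
            raise ValueError(f"lineage skips a rank for genomes {offenders}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.lineages.index)

    def taxon_at(self, genome_id: str, rank: str) -> str | None:
        """Taxon of ``genome_id`` at ``rank``; falls back to the deepest
        available shallower rank (flagged in the log) when ``rank`` is absent."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        row = self.lineages.loc[genome_id]
        val = row[rank]
        if pd.notna(val) and val != "":
            return str(val)
        for r in reversed(RANKS[: RANKS.index(rank)]):
            v = row[r]
            if pd.notna(v) and v != "":
                logger.warning(
                    "genome %s has no %s; falling back to %s=%s", genome_id, rank, r, v
                )
                return str(v)
        return None

    def lineage_of(self, genome_id: str, rank: str | None = None) -> list[str]:
        """Ranked lineage of ``genome_id``, optionally truncated at ``rank``."""
        row = self.lineages.loc[genome_id]
        upto = RANKS if rank is None else RANKS[: RANKS.index(rank) + 1]
        out = []
        for r in upto:
            v = row[r]
            if pd.isna(v) or v == "":
                break
            out.append(str(v))
        return out

    def to_tsv(self, path) -> None:
        self.lineages.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path) -> "HostTaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


@dataclass
class HostAssignment:
    """One host prediction for one query genome."""

    query_id: str
    method: str  # network | refseq_homology | tara_homology | crispr | trna
    predicted_lineage: list[str] = field(default_factory=list)
    score: float = float("nan")
    support: str = ""

    METHODS = ("network", "refseq_homology", "tara_homology", "crispr", "trna")

    def __post_init__(self) -> None:
        if self.method not in self.METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.predicted_lineage:
            raise ValueError("predicted lineage must be non-empty")

    @property
    def predicted_taxon(self) -> str:
        return self.predicted_lineage[-1]


def assignments_to_frame(assignments: list[HostAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "method": a.method,
                "predicted_taxon": a.predicted_taxon,
                "predicted_lineage": ";".join(a.predicted_lineage),
                "score": a.score,
                "support": a.support,
            }
            for a in assignments
        ],
        columns=["query_id", "method", "predicted_taxon", "predicted_lineage", "score", "support"],
    )
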