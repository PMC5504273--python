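"""Synthetic communities with known virus-host ground truth.

Every input the toolkit consumes can be generated here: virus count
matrices whose abundances are coupled to simulated host dynamics
(for the co-occurrence network and its host-prediction calibration),
all-vs-all homology hit tables with planted group structure (for the
Dice/BIONJ pipeline), and read-alignment tables with a controlled
ambiguous-read fraction (for the weighted read assignment).

Host dynamics are multivariate log-normal across samples — heavy-tailed
relative abundances of the kind marine communities show — and sequencing
is multinomial at a fixed per-sample depth. A virus tracks its host with
a tunable ``coupling``: its latent abundance is
``coupling * host + (1 - coupling) * noise`` on the linear scale, with
log-normal noise of the stated ``dispersion``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import COUNTS, AbundanceMatrix, HostTaxonomyTable

_PHYLA = ["Proteobacteria", "Cyanobacteria", "Bacteroidetes", "Actinobacteria", "Firmicutes"]


@dataclass
class SyntheticCommunity:
    """Simulated paired host/virus abundances with a truth table."""

    host_taxa: HostTaxonomyTable            # lineage per host genus
    host_abundance: pd.DataFrame            # host genera x samples, relative
    virus_truth: dict[str, str]             # virus id -> true host genus
    virus_counts: pd.DataFrame              # viruses x samples, integer counts
    coupling: float
    dispersion: float
    depth: int
    seed: int

    def counts_matrix(self) -> AbundanceMatrix:
        return AbundanceMatrix(self.virus_counts.astype(float), mode=COUNTS)

    def reference_hosts(self, n_refs_per_host: int = 2) -> HostTaxonomyTable:
        """Host-taxonomy labels for the first ``n_refs_per_host`` viruses
        of each host; the remaining viruses are unlabelled queries."""
        rows = {}
        per_host: dict[str, int] = {}
        for v, h in self.virus_truth.items():
            k = per_host.get(h, 0)
            if k < n_refs_per_host:
                rows[v] = self.host_taxa.lineages.loc[h]
                per_host[h] = k + 1
        return HostTaxonomyTable(pd.DataFrame(rows).T)

    def true_genus(self, virus_id: str) -> str:
        return self.virus_truth[virus_id]


def _host_lineages(n_hosts: int) -> HostTaxonomyTable:
    rows = {}
    for i in range(n_hosts):
        phylum = _PHYLA[i % len(_PHYLA)]
        genus = f"Genus_{i:02d}"
        rows[genus] = {
            "domain": "Bacteria",
            "phylum": phylum,
            "class": f"Class_{phylum}",
            "order": f"Order_{phylum}_{i % 2}",
            "family": f"Family_{i:02d}",
            "genus": genus,
            "species": np.nan,
        }
    return HostTaxonomyTable(pd.DataFrame(rows).T)


def simulate_community(
    n_hosts: int = 20,
    viruses_per_host: int = 3,
    n_samples: int = 120,
    coupling: float = 0.95,
    dispersion: float = 0.5,
    depth: int = 100_000,
    seed: int = 0,
    host_sigma: float = 1.0,
    host_covariance: np.ndarray | None = None,
) -> SyntheticCommunity:
    """Simulate a host community and its coupled viruses.

    Host log-abundances are drawn i.i.d. per sample from a multivariate
    normal (diagonal ``host_sigma**2`` by default, or the supplied
    covariance) and exponentiated; virus latent abundances mix the host
    signal with independent log-normal noise at weight ``1 - coupling``;
    virus counts are multinomial per sample at ``depth`` reads.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    if min(n_hosts, viruses_per_host, n_samples, depth) <= 0 or dispersion <= 0:
        raise ValueError("all simulation parameters must be positive")
    rng = np.random.default_rng(seed)
    taxa = _host_lineages(n_hosts)
    hosts = taxa.genome_ids

    if host_covariance is None:
        z = rng.normal(scale=host_sigma, size=(n_hosts, n_samples))
    else:
        z = rng.multivariate_normal(
            np.zeros(n_hosts), np.asarray(host_covariance), size=n_samples
        ).T
    h = np.exp(z)
    h /= h.sum(axis=0, keepdims=True)
    host_ab = pd.DataFrame(h, index=hosts, columns=[f"s{j:03d}" for j in range(n_samples)])

    virus_ids, truth, latent = [], {}, []
    scale = h.mean()
    for i, host in enumerate(hosts):
        for k in range(viruses_per_host):
            vid = f"vir_{host}_{k}"
            virus_ids.append(vid)
            truth[vid] = host
            noise = scale * np.exp(rng.normal(scale=dispersion, size=n_samples))
            latent.append(coupling * h[i] + (1.0 - coupling) * noise)
    latent = np.asarray(latent)
    fractions = latent / latent.sum(axis=0, keepdims=True)

    counts = np.column_stack(
        [rng.multinomial(depth, fractions[:, j]) for j in range(n_samples)]
    )
    if (counts.sum(axis=1) == 0).any():
        import logging

        logging.getLogger("viromenet").warning(
            "depth %d too small: some viruses received no reads in any sample", depth
        )
    virus_counts = pd.DataFrame(counts, index=virus_ids, columns=host_ab.columns)
    return SyntheticCommunity(
        host_taxa=taxa,
        host_abundance=host_ab,
        virus_truth=truth,
        virus_counts=virus_counts,
        coupling=coupling,
        dispersion=dispersion,
        depth=depth,
        seed=seed,
    )


@dataclass
class SyntheticHomologySet:
    """All-vs-all hit table with planted genome groups."""

    hits: pd.DataFrame            # 12-column tabular dialect
    groups: dict[str, int]        # genome id -> true group index


def simulate_homology_set(
    n_groups: int = 2,
    genomes_per_group: int = 4,
    seed: int = 0,
    self_score: float = 5000.0,
    within_similarity: tuple[float, float] = (0.5, 0.8),
    between_similarity: tuple[float, float] = (0.0, 0.05),
) -> SyntheticHomologySet:
    """Emit an all-vs-all hit table where within-group summed bitscores
    are a high fraction of the self-score and between-group a low one,
    so the planted partition separates in Dice distance."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    genomes = [
        (f"g{grp}_{k}", grp) for grp in range(n_groups) for k in range(genomes_per_group)
    ]
    rows = []

    def _hit(q, s, total_bitscore):
        # split the target summed bitscore over a few qualifying hits
        n_hits = int(rng.integers(1, 4))
        parts = rng.dirichlet(np.ones(n_hits)) * total_bitscore
        for b in parts:
            length = int(rng.integers(30, 300))
            rows.append(
                (q, s, float(rng.uniform(35, 95)), length, int(rng.integers(0, 10)),
                 0, 1, length * 3, 1, length * 3, float(10 ** rng.uniform(-50, -3)),
                 round(float(b), 1))
            )

    for qi, (q, gq) in enumerate(genomes):
        _hit(q, q, self_score)
        for si, (s, gs) in enumerate(genomes):
            if si == qi:
                continue
            lo, hi = within_similarity if gq == gs else between_similarity
            frac = rng.uniform(lo, hi)
            if frac * self_score >= 1:
                _hit(q, s, frac * self_score)

    hits = pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "percent_identity", "alignment_length",
            "mismatches", "gaps", "q_start", "q_end", "s_start", "s_end",
            "e_value", "bitscore",
        ],
    )
    return SyntheticHomologySet(hits=hits, groups=dict(genomes))


def simulate_read_alignments(
    community: SyntheticCommunity,
    ambiguous_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a community's virus counts into a read-alignment table.

    A fraction of reads per sample is ambiguous: each such read aligns
    to a genome pair drawn with probability proportional to the joint
    abundance p_i * p_j, its true origin drawn within the pair
    proportionally to relative abundance (which makes the unique-ratio
    reassignment unbiased). The remaining reads align uniquely to their
    true genome. Returns ``(table, truth_counts)``: the
    (read_id, genome_id, sample_id) table the abundance module consumes
    and the realized per-genome true read counts. With
    ``ambiguous_fraction = 0`` the truth equals ``community.virus_counts``
    exactly.
    """
    if not 0 <= ambiguous_fraction < 1:
        raise ValueError("ambiguous_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genomes = np.asarray(community.virus_counts.index)
    d = len(genomes)
    rows = []
    truth = pd.DataFrame(
        0, index=community.virus_counts.index, columns=community.virus_counts.columns
    )
    for sample in community.virus_counts.columns:
        counts = community.virus_counts[sample].to_numpy()
        n_reads = int(counts.sum())
        if n_reads == 0:
            continue
        origin = np.repeat(np.arange(d), counts)
        fractions = counts / n_reads
        ambig = np.flatnonzero(rng.random(n_reads) < ambiguous_fraction)
        true_counts = counts.copy()
        pair_of: dict[int, tuple[int, int]] = {}
        for r in ambig:
            # pair ~ p_i * p_j (i != j), origin within pair ~ relative abundance
            i = j = 0
            while i == j:
                i, j = rng.choice(d, size=2, p=fractions)
            o = i if rng.random() < fractions[i] / (fractions[i] + fractions[j]) else j
            true_counts[origin[r]] -= 1
            true_counts[o] += 1
            origin[r] = o
            pair_of[int(r)] = (int(i), int(j))
        for r, gi in enumerate(origin):
            read = f"{sample}_r{r}"
            if r in pair_of:
                for g in sorted(set(pair_of[r])):
                    rows.append((read, genomes[g], sample))
            else:
                rows.append((read, genomes[gi], sample))
        truth[sample] = true_counts
    table = pd.DataFrame(rows, columns=["read_id", "genome_id", "sample_id"])
    return table, truth
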