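"""Co-occurrence host prediction.

Virus and host abundances track each other across space and time, so two
viruses whose abundances correlate strongly tend to infect the same
host. A query virus is therefore assigned the host of the reference
virus (known host) with which it shows the strongest positive SparCC
correlation, subject to a minimum-correlation cutoff that trades
coverage for accuracy. The module also provides the two analyses used to
calibrate the method: leave-self-out accuracy of reference-vs-reference
predictions as a function of the cutoff, and a census of correlation
signs among reference pairs sharing a host.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    RANKS,
    CorrelationNetwork,
    HostAssignment,
    HostTaxonomyTable,
    assignments_to_frame,
)

logger = logging.getLogger("viromenet")

_TIE_EPS = 1e-12


def _best_reference(rho_row: pd.Series, references: list[str]) -> tuple[float, list[str]]:
    """Maximum correlation to any reference and the tied argmax set."""
    r = rho_row[references]
    best = float(r.max())
    tied = list(r.index[np.abs(r.to_numpy(dtype=float) - best) <= _TIE_EPS])
    return best, tied


def predict_hosts(
    network: CorrelationNetwork,
    hosts: HostTaxonomyTable,
    rank: str = "phylum",
    cutoff: float = 0.6,
    queries: list[str] | None = None,
) -> list[HostAssignment]:
    """Assign each unlabelled genome the host of its top-correlated reference.

    A query is assigned only when its maximum correlation to a reference
    reaches ``cutoff`` and all references tied at that maximum agree at
    ``rank`` (otherwise the tie is logged and the query abstains).
    Negative correlations are never used for prediction.
    """
    labelled = set(hosts.genome_ids)
    in_net = network.genome_ids
    references = [g for g in in_net if g in labelled]
    if queries is None:
        queries = [g for g in in_net if g not in labelled]
    if not references:
        raise ValueError("no reference genomes with host labels in the network")

    out: list[HostAssignment] = []
    for q in queries:
        best, tied = _best_reference(network.rho.loc[q], references)
        if best < cutoff:
            continue
        taxa = {hosts.taxon_at(r, rank) for r in tied}
        taxa.discard(None)
        if len(taxa) != 1:
            logger.warning(
                "query %s: %d references tied at rho=%.3f disagree at %s; abstaining",
                q, len(tied), best, rank,
            )
            continue
        ref = sorted(tied)[0]
        lineage = hosts.lineage_of(ref, rank)
        if not lineage:
            continue
        out.append(
            HostAssignment(
                query_id=q,
                method="network",
                predicted_lineage=lineage,
                score=best,
                support=f"top correlation with {ref}" + (f" (+{len(tied) - 1} tied)" if len(tied) > 1 else ""),
            )
        )
    return out


def evaluate_reference_accuracy(
    network: CorrelationNetwork,
    hosts: HostTaxonomyTable,
    rank: str = "phylum",
    cutoffs=None,
) -> pd.DataFrame:
    """Leave-self-out accuracy of the co-occurrence method on references.

    Each labelled reference is predicted from its strongest positively
    correlated *other* reference and scored correct when the two hosts
    match at ``rank``. Returns one row per cutoff with columns
    ``cutoff``, ``n_predicted`` and ``accuracy`` (NaN when nothing is
    predicted at that cutoff).
    """
    if cutoffs is None:
        cutoffs = np.arange(-1.0, 0.95, 0.05)
    references = [g for g in network.genome_ids if g in set(hosts.genome_ids)]
    if not references:
        raise ValueError("empty reference set")

    per_ref = []  # (best_rho, correct or None-for-tie-disagreement)
    for g in references:
        others = [r for r in references if r != g]
        if not others:
            continue
        best, tied = _best_reference(network.rho.loc[g], others)
        own = hosts.taxon_at(g, rank)
        taxa = {hosts.taxon_at(r, rank) for r in tied}
        taxa.discard(None)
        if len(taxa) != 1 or own is None:
            per_ref.append((best, None))
        else:
            per_ref.append((best, taxa.pop() == own))

    rows = []
    for c in np.asarray(cutoffs, dtype=float):
        scored = [ok for best, ok in per_ref if best >= c and ok is not None]
        n = len(scored)
        rows.append(
            {"cutoff": c, "n_predicted": n, "accuracy": (sum(scored) / n) if n else np.nan}
        )
    return pd.DataFrame(rows)


def same_host_correlation_census(
    network: CorrelationNetwork,
    hosts: HostTaxonomyTable,
    rank: str = "genus",
    min_abs: float = 0.3,
) -> dict[str, int]:
    """Sign census of correlations between references sharing a host.

    Pairs with |rho| below ``min_abs`` are considered too close to zero
    for a reliable sign and are excluded.
    """
    references = [g for g in network.genome_ids if g in set(hosts.genome_ids)]
    n_pos = n_neg = 0
    for i in range(len(references)):
        ti = hosts.taxon_at(references[i], rank)
        if ti is None:
            continue
        for j in range(i + 1, len(references)):
            if hosts.taxon_at(references[j], rank) != ti:
                continue
            rho = float(network.rho.loc[references[i], references[j]])
            if rho >= min_abs:
                n_pos += 1
            elif rho <= -min_abs:
                n_neg += 1
    return {"n_positive": n_pos, "n_negative": n_neg}


class NetworkHostPredictor(BaseEstimator):
    """Scikit-learn style wrapper around co-occurrence host prediction.

    Parameters
    ----------
    rank : str, default "phylum"
        Taxonomic rank at which hosts are reported and accuracy scored.
    cutoff : float, default 0.6
        Minimum SparCC correlation for a prediction.

    After :meth:`fit` (which takes the correlation network and the host
    taxonomy of the reference genomes), :meth:`predict` returns a
    DataFrame of assignments and :meth:`accuracy_curve` the leave-self-out
    calibration table.
    """

    def __init__(self, rank: str = "phylum", cutoff: float = 0.6):
        self.rank = rank
        self.cutoff = cutoff

    def fit(self, network: CorrelationNetwork, hosts: HostTaxonomyTable):
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        self.network_ = network
        self.hosts_ = hosts
        labelled = set(hosts.genome_ids)
        self.reference_ids_ = [g for g in network.genome_ids if g in labelled]
        self.query_ids_ = [g for g in network.genome_ids if g not in labelled]
        return self

    def predict(self, queries: list[str] | None = None) -> pd.DataFrame:
        assignments = predict_hosts(
            self.network_, self.hosts_, rank=self.rank, cutoff=self.cutoff, queries=queries
        )
        return assignments_to_frame(assignments)

    def accuracy_curve(self, cutoffs=None) -> pd.DataFrame:
        return evaluate_reference_accuracy(self.network_, self.hosts_, self.rank, cutoffs)

    def census(self, rank: str = "genus", min_abs: float = 0.3) -> dict[str, int]:
        return same_host_correlation_census(self.network_, self.hosts_, rank, min_abs)
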