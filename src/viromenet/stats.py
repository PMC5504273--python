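"""Virus/host-ratio statistics and group-wise differential abundance.

The virus/host ratio (VHR) of a taxon in a sample is the summed relative
abundance of viruses assigned to that host taxon divided by the host
taxon's own abundance in the paired cellular metagenome. A negative
association between VHR and host abundance — less virus per host where
the host is dense — is the abundance-profile signature of reduced lysis
at high host density (Piggyback-the-Winner); the opposite sign would
support Kill-the-Winner dynamics.

Differential abundance between two sample groups uses the two-sided
Mann-Whitney U test per feature with Benjamini-Hochberg FDR control
across features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, HostTaxonomyTable

logger = logging.getLogger("viromenet")


def virus_host_ratio(
    viral_ab: AbundanceMatrix,
    host_ab: AbundanceMatrix,
    virus_hosts: HostTaxonomyTable,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Per (host taxon, sample) VHR records.

    ``host_ab`` is indexed by host taxon names at ``rank``;
    ``virus_hosts`` maps viral genomes to their (predicted or known)
    host lineages. Viral abundance is summed over all viruses assigned
    to the taxon. Records with zero host abundance get vhr = NaN and
    ``defined = False`` (excluded from correlations, never zero-imputed).
    """
    shared = [s for s in viral_ab.sample_ids if s in set(host_ab.sample_ids)]
    if not shared:
        raise ValueError("viral and host matrices share no samples")

    taxon_of = {
        g: virus_hosts.taxon_at(g, rank)
        for g in virus_hosts.genome_ids
        if g in set(viral_ab.genome_ids)
    }
    rows = []
    for taxon in host_ab.genome_ids:
        viruses = [g for g, t in taxon_of.items() if t == taxon]
        if not viruses:
            continue
        v_sum = viral_ab.data.loc[viruses, shared].sum(axis=0)
        h = host_ab.data.loc[taxon, shared]
        for s in shared:
            hv, vv = float(h[s]), float(v_sum[s])
            defined = hv > 0
            rows.append(
                {
                    "taxon": taxon,
                    "rank": rank,
                    "sample_id": s,
                    "host_abundance": hv,
                    "viral_abundance": vv,
                    "vhr": vv / hv if defined else np.nan,
                    "defined": defined,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        n_undef = int((~out["defined"]).sum())
        if n_undef:
            logger.warning("%d VHR records undefined (zero host abundance)", n_undef)
    return out


def vhr_association(records: pd.DataFrame, min_records: int = 5) -> tuple[pd.DataFrame, float, float]:
    """Spearman correlation of host abundance vs VHR, per taxon and pooled.

    Taxa with fewer than ``min_records`` defined records are skipped.
    Returns (per-taxon table, pooled rho, pooled p). Constant inputs
    give NaN correlations (flagged in the log).
    """
    ok = records[records["defined"]]
    rows = []
    for taxon, grp in ok.groupby("taxon"):
        if len(grp) < min_records:
            continue
        if grp["host_abundance"].nunique() < 2 or grp["vhr"].nunique() < 2:
            logger.warning("taxon %s: constant vector, correlation undefined", taxon)
            rows.append({"taxon": taxon, "n": len(grp), "rho": np.nan, "p": np.nan})
            continue
        rho, p = sps.spearmanr(grp["host_abundance"], grp["vhr"])
        rows.append({"taxon": taxon, "n": len(grp), "rho": float(rho), "p": float(p)})
    per_taxon = pd.DataFrame(rows, columns=["taxon", "n", "rho", "p"])
    if (
        len(ok) >= min_records
        and ok["host_abundance"].nunique() > 1
        and ok["vhr"].nunique() > 1
    ):
        pooled_rho, pooled_p = sps.spearmanr(ok["host_abundance"], ok["vhr"])
    else:
        pooled_rho, pooled_p = np.nan, np.nan
    return per_taxon, float(pooled_rho), float(pooled_p)


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided U-test p; exact enumeration for small tie-free groups,
    tie-corrected normal approximation otherwise."""
    small = len(a) <= 8 and len(b) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


class MannWhitneyEnrichment(BaseEstimator):
    """Per-feature two-group Mann-Whitney test with BH-FDR (sklearn style).

    Parameters
    ----------
    alpha : float, default 0.05
        Features with BH q-value below ``alpha`` are flagged significant.

    Attributes (after ``fit(X, y)`` with X samples x features and y the
    two-level group labels)
    ----------
    pvalues_, qvalues_ : ndarray per feature
    significant_ : boolean ndarray (q < alpha)
    enriched_group_ : array of group labels (higher median; ties broken
        by higher mean; remaining ties flagged as "tied")
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        levels = np.unique(y)
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {list(levels)}")
        ga, gb = X[y == levels[0]], X[y == levels[1]]
        if len(ga) < 3 or len(gb) < 3:
            raise ValueError("each group needs at least 3 samples")

        n_features = X.shape[1]
        p = np.empty(n_features)
        enriched = np.empty(n_features, dtype=object)
        for k in range(n_features):
            a, b = ga[:, k], gb[:, k]
            p[k] = _mannwhitney_p(a, b)
            med_a, med_b = np.median(a), np.median(b)
            if med_a != med_b:
                enriched[k] = levels[0] if med_a > med_b else levels[1]
            elif a.mean() != b.mean():
                enriched[k] = levels[0] if a.mean() > b.mean() else levels[1]
            else:
                enriched[k] = "tied"
        _, q, _, _ = multipletests(p, method="fdr_bh")
        self.groups_ = levels
        self.pvalues_ = p
        self.qvalues_ = q
        self.significant_ = q < self.alpha
        self.enriched_group_ = enriched
        self.n_features_in_ = n_features
        return self

    def results_(self) -> pd.DataFrame:
        names = getattr(self, "feature_names_in_", np.arange(self.n_features_in_))
        return pd.DataFrame(
            {
                "feature_id": names,
                "group_enriched": self.enriched_group_,
                "p_raw": self.pvalues_,
                "q_fdr": self.qvalues_,
                "significant": self.significant_,
            }
        )


def differential_abundance(
    matrix: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Feature x sample matrix vs a two-level sample grouping.

    Returns the long results table (feature_id, group_enriched, p_raw,
    q_fdr, significant)."""
    samples = [s for s in matrix.columns if s in groups.index]
    if not samples:
        raise ValueError("no overlap between matrix samples and group labels")
    est = MannWhitneyEnrichment(alpha=alpha).fit(matrix[samples].T, groups.loc[samples].to_numpy())
    return est.results_()
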