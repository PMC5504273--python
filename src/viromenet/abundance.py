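"""Genome x sample abundance profiling from read alignments.

Multi-mapped ("ambiguous") reads are reassigned with a weighted score:
within each sample, unique-read counts per genome are tallied first, and
each ambiguous read is then split across its candidate genomes in
proportion to those unique counts. An ambiguous read whose candidates all
lack unique reads is split equally. Total assigned mass per sample equals
the number of distinct reads.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import COUNTS, RELATIVE, AbundanceMatrix

logger = logging.getLogger("viromenet")

ALIGNMENT_COLUMNS = ["read_id", "genome_id", "sample_id"]


def _validate_alignments(alignments: pd.DataFrame) -> pd.DataFrame:
    if alignments.empty:
        raise ValueError("alignment table is empty")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in alignments.columns]
    if missing:
        raise ValueError(f"alignment table lacks columns {missing}")
    dup = alignments.duplicated(subset=ALIGNMENT_COLUMNS)
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (read_id, genome_id, sample_id) rows"
        )
    return alignments


def assign_reads(alignments: pd.DataFrame) -> AbundanceMatrix:
    """Weighted read-to-genome assignment.

    Parameters
    ----------
    alignments : DataFrame with columns read_id, genome_id, sample_id.
        One row per (read, genome) alignment; a read with rows for more
        than one genome in its sample is ambiguous.

    Returns
    -------
    AbundanceMatrix in counts mode. Per sample, each unambiguous read
    contributes 1.0 to its genome; an ambiguous read hitting genomes
    g1..gk contributes u_i / sum(u_j) to g_i where u_i is the genome's
    unambiguous-read count in that sample (equal split 1/k when all
    u_j = 0).
    """
    alignments = _validate_alignments(alignments)

    genomes = sorted(alignments["genome_id"].unique())
    samples = sorted(alignments["sample_id"].unique())
    g_index = {g: i for i, g in enumerate(genomes)}
    s_index = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(genomes), len(samples)), dtype=float)

    n_hits = alignments.groupby(["sample_id", "read_id"])["genome_id"].transform("size")
    unique_rows = alignments[n_hits == 1]
    ambig_rows = alignments[n_hits > 1]

    # pass 1: unique reads define the per-sample anchor counts
    uniq_counts = unique_rows.groupby(["sample_id", "genome_id"]).size()
    for (s, g), n in uniq_counts.items():
        mat[g_index[g], s_index[s]] += float(n)

    # pass 2: allocate each ambiguous read once, proportionally to anchors
    for (s, _read), grp in ambig_rows.groupby(["sample_id", "read_id"], sort=False):
        cand = grp["genome_id"].to_numpy()
        u = np.array([uniq_counts.get((s, g), 0) for g in cand], dtype=float)
        total = u.sum()
        weights = u / total if total > 0 else np.full(len(cand), 1.0 / len(cand))
        j = s_index[s]
        for g, w in zip(cand, weights):
            mat[g_index[g], j] += w

    return AbundanceMatrix(pd.DataFrame(mat, index=genomes, columns=samples), mode=COUNTS)


def to_relative(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Column-normalize a counts matrix to per-sample relative abundances.

    All-zero sample columns are preserved as zero (logged)."""
    if matrix.mode != COUNTS:
        raise ValueError("to_relative expects a counts-mode matrix")
    vals = matrix.values
    sums = vals.sum(axis=0)
    zero_cols = sums == 0
    if zero_cols.any():
        logger.warning(
            "%d all-zero sample columns left as zero: %s",
            int(zero_cols.sum()),
            list(np.asarray(matrix.sample_ids)[zero_cols]),
        )
    safe = np.where(zero_cols, 1.0, sums)
    rel = vals / safe
    return AbundanceMatrix(
        pd.DataFrame(rel, index=matrix.genome_ids, columns=matrix.sample_ids),
        mode=RELATIVE,
    )


def filter_by_prevalence(matrix: AbundanceMatrix, min_fraction: float = 0.4) -> AbundanceMatrix:
    """Drop genomes detected (> 0) in fewer than ``min_fraction`` of samples.

    Mirrors the network-inference prevalence filter: genomes present in
    <40% of samples produce spurious correlations from sparse counts.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    vals = matrix.values
    n_samples = vals.shape[1]
    detected = (vals > 0).sum(axis=1)
    keep = detected >= min_fraction * n_samples
    if not keep.any():
        logger.warning("prevalence filter removed every genome")
    return AbundanceMatrix(matrix.data.loc[keep], mode=matrix.mode)


def read_alignment_tsv(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read the 4-column TSV alignment dialect.

    Columns: read_id, genome_id, sample_id, n_alignments (the last is
    informational and optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if sample_id is not None and "sample_id" not in df.columns:
        df["sample_id"] = sample_id
    return df[[c for c in df.columns if c in ALIGNMENT_COLUMNS + ["n_alignments"]]]


def read_alignment_sam(path, sample_id: str) -> pd.DataFrame:
    """Extract (read_id, genome_id, sample_id) rows from a SAM/BAM file.

    Multi-mapped records (identical query names mapped to several
    references) define ambiguity; unmapped records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            rows.append((rec.query_name, rec.reference_name, sample_id))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    # a read aligned twice to the same genome counts once
    return df.drop_duplicates(subset=ALIGNMENT_COLUMNS, ignore_index=True)
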