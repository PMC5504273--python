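"""Alignment-evidence host prediction: four deterministic filters.

Each strategy consumes a precomputed hit table (the standard 12-column
tabular alignment dialect, plus optional extra columns) and emits host
assignments:

1. genome homology — best nucleotide hit above 80% identity over at
   least 1,000 nt against a microbial-genome database;
2. environmental-contig homology — the same alignment filter against
   contigs whose taxonomy was called by hierarchical bitscore voting;
3. CRISPR spacers — full-length spacer matches with at most two
   mismatches/gaps, host = the spacer's source organism;
4. tRNA matches — best hit with >= 90% identity and >= 90% coverage of
   the tRNA.

"Best hit" always means maximum bitscore, ties broken by lower e-value
then lexicographic subject id, so outputs are deterministic and
order-insensitive.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import (
    RANKS,
    HostAssignment,
    HostTaxonomyTable,
    assignments_to_frame,
)

logger = logging.getLogger("viromenet")

OUTFMT6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gaps", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bitscore",
]


def read_hit_table(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a headerless 12-column tabular alignment file (optionally with
    extra trailing columns such as subject_coverage or query_length)."""
    names = OUTFMT6_COLUMNS + (extra_columns or [])
    return pd.read_csv(path, sep="\t", header=None, names=names)


def _best_hits(hits: pd.DataFrame, by: str = "query_id") -> pd.DataFrame:
    """One row per group: max bitscore, ties by lower e-value then subject id."""
    ordered = hits.sort_values(
        ["bitscore", "e_value", "subject_id"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.drop_duplicates(subset=by, keep="first")


def host_by_genome_homology(
    hits: pd.DataFrame,
    hosts: HostTaxonomyTable,
    min_identity: float = 80.0,
    min_length: int = 1000,
    method: str = "refseq_homology",
) -> list[HostAssignment]:
    """Strategy 1: best hit with identity strictly above ``min_identity``
    over an alignment of at least ``min_length`` nucleotides."""
    ok = hits[(hits["percent_identity"] > min_identity) & (hits["alignment_length"] >= min_length)]
    out = []
    for _, row in _best_hits(ok).iterrows():
        subject = row["subject_id"]
        if subject not in hosts.lineages.index:
            logger.warning("subject %s has no taxonomy; hit skipped", subject)
            continue
        out.append(
            HostAssignment(
                query_id=row["query_id"],
                method=method,
                predicted_lineage=hosts.lineage_of(subject),
                score=float(row["bitscore"]),
                support=f"{row['percent_identity']:.1f}% id over {int(row['alignment_length'])} nt vs {subject}",
            )
        )
    return out


def classify_contig_taxonomy(
    protein_hits: pd.DataFrame,
    consistency: float = 0.8,
    min_total_bitscore: float = 1000.0,
    max_e: float = 1e-5,
    min_identity: float = 30.0,
) -> dict[str, list[str]]:
    """Hierarchical bitscore-voting taxonomy of contigs.

    ``protein_hits`` holds one best hit per protein with columns
    contig_id, protein_id, bitscore, e_value, percent_identity and
    subject_lineage (semicolon-joined ranked taxa, domain first). Hits
    with e_value >= ``max_e`` or identity <= ``min_identity`` are
    discarded first. A contig whose surviving total bitscore is below
    ``min_total_bitscore`` stays unclassified. Otherwise ranks are fixed
    from domain downward while a single taxon holds at least
    ``consistency`` of the contig's (post-filter) total bitscore.

    Returns contig_id -> lineage prefix ([] when unclassified at domain).
    """
    ok = protein_hits[
        (protein_hits["e_value"] < max_e) & (protein_hits["percent_identity"] > min_identity)
    ].copy()
    # contigs whose every hit fails the pre-filter stay unclassified
    result: dict[str, list[str]] = {c: [] for c in protein_hits["contig_id"].unique()}
    for contig, grp in ok.groupby("contig_id"):
        total = grp["bitscore"].sum()
        if total < min_total_bitscore:
            result[contig] = []
            continue
        lineages = [str(l).split(";") for l in grp["subject_lineage"]]
        scores = grp["bitscore"].to_numpy(dtype=float)
        fixed: list[str] = []
        for depth in range(len(RANKS)):
            votes: dict[str, float] = {}
            for lin, s in zip(lineages, scores):
                if len(lin) <= depth:
                    continue
                if lin[:depth] != fixed:
                    continue
                votes[lin[depth]] = votes.get(lin[depth], 0.0) + s
            winner = max(votes, key=votes.get) if votes else None
            if winner is None or votes[winner] < consistency * total:
                break
            fixed.append(winner)
        result[contig] = fixed
    return result


NON_HOST_DOMAINS = {"Viruses", "Eukaryota"}


def host_by_contig_homology(
    hits: pd.DataFrame,
    contig_lineages: dict[str, list[str]],
    min_identity: float = 80.0,
    min_length: int = 1000,
) -> list[HostAssignment]:
    """Strategy 2: strategy 1's alignment filter against environmental
    contigs labelled by :func:`classify_contig_taxonomy`.

    Contigs unclassified at domain, or viral/eukaryotic, never yield a
    host."""
    ok = hits[(hits["percent_identity"] > min_identity) & (hits["alignment_length"] >= min_length)]
    usable = ok[
        ok["subject_id"].map(
            lambda s: bool(contig_lineages.get(s)) and contig_lineages[s][0] not in NON_HOST_DOMAINS
        )
    ]
    out = []
    for _, row in _best_hits(usable).iterrows():
        lineage = contig_lineages[row["subject_id"]]
        out.append(
            HostAssignment(
                query_id=row["query_id"],
                method="tara_homology",
                predicted_lineage=lineage,
                score=float(row["bitscore"]),
                support=f"contig {row['subject_id']} ({';'.join(lineage)})",
            )
        )
    return out


def host_by_crispr(
    spacer_hits: pd.DataFrame,
    hosts: HostTaxonomyTable,
    spacer_sources: dict[str, str],
    max_errors: int = 2,
) -> list[HostAssignment]:
    """Strategy 3: CRISPR spacer matches.

    ``spacer_hits`` are spacer-vs-virus alignments (query = spacer,
    subject = viral genome) carrying a ``query_length`` column with the
    spacer length. A hit is accepted when mismatches + gaps <= ``max_errors``
    and the alignment covers the full spacer (length >= spacer length
    minus gaps). The host is the spacer's source organism; multiple
    concordant spacers raise the support count, conflicting phyla are
    reported with a conflict flag.
    """
    if "query_length" not in spacer_hits.columns:
        raise ValueError("spacer hit table needs a 'query_length' column (spacer length)")
    errs = spacer_hits["mismatches"] + spacer_hits["gaps"]
    full = spacer_hits["alignment_length"] >= spacer_hits["query_length"] - spacer_hits["gaps"]
    ok = spacer_hits[(errs <= max_errors) & full]

    out: list[HostAssignment] = []
    for virus, grp in ok.groupby("subject_id"):
        by_source: dict[str, int] = {}
        for spacer in grp["query_id"]:
            source = spacer_sources.get(spacer)
            if source is None or source not in hosts.lineages.index:
                logger.warning("spacer %s has no source taxonomy; hit skipped", spacer)
                continue
            by_source[source] = by_source.get(source, 0) + 1
        if not by_source:
            continue
        phyla = {hosts.taxon_at(s, "phylum") for s in by_source}
        conflict = len(phyla - {None}) > 1
        if conflict:
            logger.warning("virus %s: CRISPR spacers from conflicting phyla %s", virus, phyla)
        for source, n in sorted(by_source.items()):
            out.append(
                HostAssignment(
                    query_id=virus,
                    method="crispr",
                    predicted_lineage=hosts.lineage_of(source),
                    score=float(n),
                    support=f"{n} spacer(s) from {source}" + ("; CONFLICT across phyla" if conflict else ""),
                )
            )
    return out


def host_by_trna(
    trna_hits: pd.DataFrame,
    hosts: HostTaxonomyTable,
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> list[HostAssignment]:
    """Strategy 4: best tRNA hit with >= 90% identity and >= 90% coverage.

    ``subject_coverage`` holds the aligned fraction of the tRNA query
    (0-1). An optional ``contig_id`` column attributes the tRNA to its
    viral contig; otherwise the query id is used.
    """
    if "subject_coverage" not in trna_hits.columns:
        raise ValueError("tRNA hit table needs a 'subject_coverage' column (tRNA coverage, 0-1)")
    ok = trna_hits[
        (trna_hits["percent_identity"] >= min_identity)
        & (trna_hits["subject_coverage"] >= min_coverage)
    ]
    by = "contig_id" if "contig_id" in ok.columns else "query_id"
    out = []
    for _, row in _best_hits(ok, by=by).iterrows():
        subject = row["subject_id"]
        if subject not in hosts.lineages.index:
            logger.warning("subject %s has no taxonomy; tRNA hit skipped", subject)
            continue
        out.append(
            HostAssignment(
                query_id=row[by],
                method="trna",
                predicted_lineage=hosts.lineage_of(subject),
                score=float(row["bitscore"]),
                support=f"tRNA hit vs {subject}: {row['percent_identity']:.1f}% id, "
                f"{100 * row['subject_coverage']:.0f}% coverage",
            )
        )
    return out


def consolidate_predictions(assignments: list[HostAssignment]) -> pd.DataFrame:
    """Taxon x method table of assignment counts, sorted by row totals.

    Shape of a per-method host-assignment summary: one row per predicted
    taxon, one column per prediction method, cells counting distinct
    queries. The long per-query table is what :func:`assignments_to_frame`
    returns; this is its census."""
    frame = assignments_to_frame(assignments)
    if frame.empty:
        return pd.DataFrame(columns=list(HostAssignment.METHODS))
    counts = (
        frame.drop_duplicates(subset=["query_id", "method", "predicted_taxon"])
        .groupby(["predicted_taxon", "method"])
        .size()
        .unstack(fill_value=0)
    )
    for m in HostAssignment.METHODS:
        if m not in counts.columns:
            counts[m] = 0
    counts = counts[list(HostAssignment.METHODS)]
    return counts.loc[counts.sum(axis=1).sort_values(ascending=False, kind="mergesort").index]
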