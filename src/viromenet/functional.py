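"""Abundance-weighted functional (KO) profiles.

The functional profile of a sample sums, for each KO, the copy number of
that KO in every genome multiplied by the genome's abundance in the
sample: in a sample with genomes A, B, C at abundances 1, 5 and 10, each
encoding a KO once, that KO's abundance is 1 + 5 + 10 = 16. The profile
is exactly linear in the abundance matrix.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import AbundanceMatrix

logger = logging.getLogger("viromenet")


def sample_ko_profile(
    annotations: pd.DataFrame,
    abundance: AbundanceMatrix,
    relative: bool = False,
) -> pd.DataFrame:
    """KO x sample profile: profile[ko, s] = sum_g copies(g, ko) * abundance[g, s].

    ``annotations`` has columns genome_id, ko_id, copies (unique
    (genome, ko) pairs, copies >= 1). Genomes annotated but absent from
    the abundance matrix are warned about and ignored. With
    ``relative=True`` each sample column is renormalized to sum to 1.
    """
    if annotations.duplicated(subset=["genome_id", "ko_id"]).any():
        raise ValueError("(genome_id, ko_id) pairs must be unique")
    if (annotations["copies"] < 1).any():
        raise ValueError("copies must be >= 1")
    known = set(abundance.genome_ids)
    extra = sorted(set(annotations["genome_id"]) - known)
    if extra:
        logger.warning("%d annotated genomes absent from abundance matrix: %s", len(extra), extra[:5])
        annotations = annotations[annotations["genome_id"].isin(known)]

    copies = annotations.pivot(index="ko_id", columns="genome_id", values="copies").fillna(0.0)
    copies = copies.reindex(columns=abundance.genome_ids, fill_value=0.0)
    profile = copies.to_numpy() @ abundance.values
    out = pd.DataFrame(profile, index=copies.index, columns=abundance.sample_ids)
    if relative:
        sums = out.sum(axis=0)
        out = out.div(sums.where(sums > 0, 1.0), axis=1)
    return out


def annotate_best_hits(protein_hits: pd.DataFrame, max_e: float = 1e-5) -> pd.DataFrame:
    """Best-hit KO annotation per protein.

    ``protein_hits`` has columns genome_id, protein_id, ko_id, bitscore,
    e_value. Per protein the single best hit (max bitscore, ties by
    lower e-value then lexicographic KO id) is kept when its e-value is
    within ``max_e``; copies then count proteins per (genome, ko).
    """
    ordered = protein_hits.sort_values(
        ["bitscore", "e_value", "ko_id"], ascending=[False, True, True], kind="mergesort"
    )
    best = ordered.drop_duplicates(subset=["genome_id", "protein_id"], keep="first")
    best = best[best["e_value"] <= max_e]
    return (
        best.groupby(["genome_id", "ko_id"])
        .size()
        .rename("copies")
        .reset_index()
    )
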