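"""Dice-distance phylogenomics.

Whole-genome similarity between viral genomes is summarized from an
all-vs-all translated search: after discarding weak hits (identity
< 30%, aligned length < 30 aa, e-value > 0.01), the summed bitscore
S[A][B] of all hits of genome A against genome B yields the Dice
distance

    D(A, B) = 1 - 2 * AB / (AA + BB),

0 for identical genomes, 1 for genomes sharing no homologues. The
directional sums are symmetrized as AB_sym = (S[A][B] + S[B][A]) / 2.
Distances are clustered into an unrooted tree with the BIONJ
neighbour-joining variant, which picks the pair minimizing the standard
Q criterion but reduces the matrix with a variance-minimizing weight
lambda in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("viromenet")


def filter_homology_hits(
    hits: pd.DataFrame,
    min_identity: float = 30.0,
    min_length: int = 30,
    max_e: float = 0.01,
) -> pd.DataFrame:
    """Keep hits with identity >= 30%, aligned length >= 30 aa, e <= 0.01."""
    return hits[
        (hits["percent_identity"] >= min_identity)
        & (hits["alignment_length"] >= min_length)
        & (hits["e_value"] <= max_e)
    ]


@dataclass
class GenomeSimilarity:
    """Summed-bitscore similarity matrix; S[A][A] is the self-score AA."""

    S: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.S.index)


def genome_similarity(hits: pd.DataFrame, require_self: bool = True) -> GenomeSimilarity:
    """Sum filtered bitscores into S[query][subject].

    Genomes lacking self-hits are dropped with a warning (their
    self-score AA, the Dice denominator, is undefined)."""
    sums = hits.groupby(["query_id", "subject_id"])["bitscore"].sum()
    ids = sorted(set(hits["query_id"]) | set(hits["subject_id"]))
    S = pd.DataFrame(0.0, index=ids, columns=ids)
    for (q, s), b in sums.items():
        S.loc[q, s] = float(b)
    if require_self:
        selfless = [g for g in ids if S.loc[g, g] <= 0]
        if selfless:
            logger.warning("dropping %d genomes without self-hits: %s", len(selfless), selfless[:5])
            keep = [g for g in ids if g not in set(selfless)]
            S = S.loc[keep, keep]
    return GenomeSimilarity(S)


def dice_distance_matrix(sim: GenomeSimilarity) -> pd.DataFrame:
    """D = 1 - 2 * AB_sym / (AA + BB), clamped to [0, 1]; zero diagonal."""
    S = sim.S.to_numpy(dtype=float)
    self_scores = np.diag(S)
    if (self_scores <= 0).any():
        bad = [sim.ids[i] for i in np.flatnonzero(self_scores <= 0)]
        raise ValueError(f"genomes lack self-hits (AA <= 0): {bad}")
    ab = (S + S.T) / 2.0
    denom = self_scores[:, None] + self_scores[None, :]
    D = 1.0 - 2.0 * ab / denom
    D = np.clip(D, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sim.ids, columns=sim.ids)


def _validate_distance(D: pd.DataFrame) -> np.ndarray:
    arr = D.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or arr.shape[0] < 3:
        raise ValueError("distance matrix must be square with dimension >= 3")
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return arr


def bionj_tree(D: pd.DataFrame) -> dendropy.Tree:
    """Build an unrooted BIONJ tree from a symmetric distance matrix.

    Agglomeration follows neighbour joining (Q-criterion pair choice and
    the standard branch-length formulas); the reduced distances to the
    new node use the BIONJ weight

        lambda = 1/2 + sum_k (v_jk - v_ik) / (2 (r - 2) v_ij),

    clamped to [0, 1], where v is the running variance matrix
    (initialized to D). Negative branch lengths are clamped to zero and
    the total deficit logged.
    """
    arr = _validate_distance(D)
    ids = list(D.index)
    n = len(ids)

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)

    d = arr.copy()
    v = arr.copy()
    active = list(range(n))
    clamped_total = 0.0

    def _edge(child: dendropy.Node, parent: dendropy.Node, length: float) -> None:
        nonlocal clamped_total
        if length < 0:
            clamped_total += -length
            length = 0.0
        parent.add_child(child)
        child.edge.length = float(length)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = dij / 2.0 + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li

        others = [k for k in active if k != i and k != j]
        if v[i, j] > 1e-12:
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (2.0 * (r - 2) * v[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = dendropy.Node()
        _edge(nodes[i], parent, li)
        _edge(nodes[j], parent, lj)

        # reuse slot i for the new node, retire slot j
        for k in others:
            dk = lam * (d[i, k] - li) + (1.0 - lam) * (d[j, k] - lj)
            vk = lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * v[i, j]
            d[i, k] = d[k, i] = dk
            v[i, k] = v[k, i] = vk
        nodes[i] = parent
        active.remove(j)

    # join the last three clusters at a central node (unrooted)
    i, j, k = active
    center = dendropy.Node()
    _edge(nodes[i], center, (d[i, j] + d[i, k] - d[j, k]) / 2.0)
    _edge(nodes[j], center, (d[i, j] + d[j, k] - d[i, k]) / 2.0)
    _edge(nodes[k], center, (d[i, k] + d[j, k] - d[i, j]) / 2.0)

    if clamped_total > 0:
        logger.warning("clamped negative branch lengths; total deficit %.3g", clamped_total)

    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def extract_clusters(tree: dendropy.Tree, max_depth: float) -> list[list[str]]:
    """Cut the tree into maximal clades whose leaf-to-leaf path diameter
    is at most ``max_depth``; returns the leaf-label partition."""
    if max_depth < 0:
        raise ValueError("max_depth must be non-negative")

    # the tree is unrooted; root it on its longest edge (the deepest
    # split) so that well-separated groups become clades of the walk
    tree = tree.clone(depth=1)
    longest = None
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.tail_node is not None:
            if longest is None or edge.length > longest.length:
                longest = edge
    if longest is not None and longest.head_node.parent_node is not tree.seed_node:
        tree.reroot_at_edge(longest, length1=longest.length / 2.0, length2=longest.length / 2.0)

    depth: dict[int, float] = {}      # max root-ward leaf distance within subtree
    diameter: dict[int, float] = {}   # max leaf-to-leaf path within subtree

    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            depth[id(node)] = 0.0
            diameter[id(node)] = 0.0
            continue
        reach = [depth[id(c)] + (c.edge.length or 0.0) for c in kids]
        depth[id(node)] = max(reach)
        best_two = sorted(reach, reverse=True)[:2]
        through = sum(best_two) if len(best_two) == 2 else best_two[0]
        diameter[id(node)] = max([diameter[id(c)] for c in kids] + [through])

    clusters: list[list[str]] = []

    def _walk(node: dendropy.Node) -> None:
        if diameter[id(node)] <= max_depth:
            clusters.append(sorted(l.taxon.label for l in node.leaf_iter()))
        else:
            for c in node.child_nodes():
                _walk(c)

    _walk(tree.seed_node)
    return clusters


def distance_to_phylip(D: pd.DataFrame, path) -> None:
    """Write a square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(D)}\n")
        for name, row in D.iterrows():
            fh.write(str(name) + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
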