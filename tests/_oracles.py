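"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results with naive loops (or an external
library) rather than calling the package's own code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sparcc_oracle(counts: np.ndarray, n_inference: int, n_exclusion: int,
                  threshold: float, seed: int) -> np.ndarray:
    """Loop-level reimplementation of the SparCC equations.

    counts: genomes x samples integers. Returns the median correlation
    matrix over ``n_inference`` Dirichlet resamplings.
    """
    rng = np.random.default_rng(seed)
    d, n = counts.shape
    all_rho = []
    for _ in range(n_inference):
        # Dirichlet(counts+1) per sample, drawn column by column
        frac = np.empty((d, n))
        for s in range(n):
            frac[:, s] = rng.dirichlet(counts[:, s] + 1.0)
        # log-ratio variances, pair by pair, textbook sample variance
        t = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                if i == j:
                    continue
                lr = [math.log(frac[i, s] / frac[j, s]) for s in range(n)]
                mean = sum(lr) / n
                t[i, j] = sum((x - mean) ** 2 for x in lr) / (n - 1)

        def solve(excluded):
            m = np.zeros((d, d))
            rhs = np.zeros(d)
            for i in range(d):
                for j in range(d):
                    if i == j or frozenset((i, j)) in excluded:
                        continue
                    m[i, i] += 1.0
                    m[i, j] = 1.0
                    rhs[i] += t[i, j]
            w2 = np.linalg.solve(m, rhs)
            return np.where(w2 <= 0, 1e-8, w2)

        def corr(w2):
            rho = np.ones((d, d))
            for i in range(d):
                for j in range(d):
                    if i != j:
                        r = (w2[i] + w2[j] - t[i, j]) / (2.0 * math.sqrt(w2[i] * w2[j]))
                        rho[i, j] = max(-1.0, min(1.0, r))
            return rho

        excluded: set[frozenset] = set()
        partners = {i: d - 1 for i in range(d)}
        rho = corr(solve(excluded))
        for _ in range(n_exclusion):
            best, bi, bj = 0.0, -1, -1
            for i in range(d):
                for j in range(i + 1, d):
                    if frozenset((i, j)) in excluded:
                        continue
                    if abs(rho[i, j]) > best:
                        best, bi, bj = abs(rho[i, j]), i, j
            if best <= threshold or bi < 0:
                break
            if partners[bi] <= 2 or partners[bj] <= 2:
                break
            excluded.add(frozenset((bi, bj)))
            partners[bi] -= 1
            partners[bj] -= 1
            rho = corr(solve(excluded))
        all_rho.append(rho)
    return np.median(np.asarray(all_rho), axis=0)


def bh_stepup_oracle(pvalues: list[float]) -> list[float]:
    """Brute-force Benjamini-Hochberg step-up q-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q


def mannwhitney_exact_oracle(a: list[float], b: list[float]) -> float:
    """Two-sided U-test p-value by exhaustive enumeration of group labels."""
    pooled = list(a) + list(b)
    na = len(a)

    def ustat(idx_a):
        u = 0
        set_a = set(idx_a)
        for i in idx_a:
            for j in range(len(pooled)):
                if j in set_a:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    observed = ustat(range(na))
    n_total = 0
    n_extreme = 0
    mu = na * (len(b)) / 2.0
    for combo in itertools.combinations(range(len(pooled)), na):
        u = ustat(combo)
        n_total += 1
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


def nj_oracle_newick(D: np.ndarray, ids: list[str]) -> str:
    """Plain neighbour-joining via scikit-bio, as an independent tree oracle."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(D, ids))
    return str(tree)
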