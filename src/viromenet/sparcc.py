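"""SparCC-style compositional correlation inference, from scratch.

Read counts from a sequencing run carry only relative information, so
Pearson correlations between raw fractions are dominated by the closure
constraint. SparCC instead works with log-ratio variances
t_ij = Var(log x_i / x_j), which are invariant to per-sample scaling,
and inverts them to per-genome basis variances w2_i under a sparsity
assumption (most pairs uncorrelated):

    sum_j t_ij  ~=  (d - 1) * w2_i + sum_{j != i} w2_j

Correlations follow as rho_ij = (w2_i + w2_j - t_ij) / (2 w_i w_j).
Strongly correlated pairs violate the sparsity assumption, so the
strongest pair above a threshold is iteratively excluded from the linear
system and the basis re-solved ("exclusion iterations"). The whole
procedure is repeated over several Dirichlet resamplings of the
fractions ("inference iterations") and the element-wise median taken.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import COUNTS, AbundanceMatrix, CorrelationNetwork

logger = logging.getLogger("viromenet")

_OMEGA_FLOOR = 1e-8


def estimate_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Posterior fractions for one counts matrix (genomes x samples).

    Per sample, fractions are drawn from Dirichlet(counts + 1) — a flat
    prior posterior that keeps zero counts usable. Columns sum to 1.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(counts, np.round(counts), atol=1e-9):
        raise ValueError(
            "counts must be integers; pass a counts-mode matrix "
            "(round weighted counts first if needed)"
        )
    # gamma representation of the Dirichlet, vectorized over samples
    g = rng.gamma(shape=counts + 1.0)
    return g / g.sum(axis=0, keepdims=True)


def logratio_variance_matrix(fractions: np.ndarray, ddof: int = 1) -> np.ndarray:
    """t[i, j] = variance over samples of log(x_i / x_j).

    ``fractions`` is genomes x samples, strictly positive; at least 3
    samples are required for a usable variance.
    """
    x = np.asarray(fractions, dtype=float)
    if (x <= 0).any():
        raise ValueError("fractions must be strictly positive")
    if x.shape[1] < 3:
        raise ValueError("log-ratio variances need at least 3 samples")
    lx = np.log(x)
    cov = np.cov(lx, ddof=ddof)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def solve_basis_variances(
    t: np.ndarray, excluded_pairs: set[tuple[int, int]] | None = None
) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    Excluded pairs are removed from both the row sums and the coefficient
    matrix. Non-positive solutions are clamped to 1e-8 (logged).
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    for i, j in excluded_pairs or ():
        include[i, j] = include[j, i] = False

    m = include.astype(float)
    np.fill_diagonal(m, include.sum(axis=1))
    rhs = (t * include).sum(axis=1)
    try:
        omega2 = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"basis-variance system singular (d={d}, "
            f"{len(excluded_pairs or ())} excluded pairs)"
        ) from err
    bad = omega2 <= 0
    if bad.any():
        logger.warning("clamped %d non-positive basis variances to %g", int(bad.sum()), _OMEGA_FLOOR)
        omega2 = np.where(bad, _OMEGA_FLOOR, omega2)
    return omega2


def correlations_from_basis(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """rho_ij = (w2_i + w2_j - t_ij) / (2 w_i w_j), clamped to [-1, 1]."""
    w = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _single_inference(
    t: np.ndarray, n_exclusion: int, exclusion_threshold: float
) -> np.ndarray:
    d = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    partners = np.full(d, d - 1)
    omega2 = solve_basis_variances(t, excluded)
    rho = correlations_from_basis(t, omega2)
    for _ in range(n_exclusion):
        mag = np.abs(rho)
        np.fill_diagonal(mag, 0.0)
        for i, j in excluded:
            mag[i, j] = mag[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        if mag[i, j] <= exclusion_threshold:
            break
        if partners[i] <= 2 or partners[j] <= 2:
            logger.warning(
                "stopping exclusions: removing pair (%d, %d) would isolate a genome", i, j
            )
            break
        excluded.add((int(i), int(j)))
        partners[i] -= 1
        partners[j] -= 1
        omega2 = solve_basis_variances(t, excluded)
        rho = correlations_from_basis(t, omega2)
    return rho


class SparCC(BaseEstimator):
    """Compositional correlation estimator (scikit-learn interface).

    Parameters
    ----------
    n_inference : int, default 10
        Number of Dirichlet fraction resamplings; the final correlation
        matrix is the element-wise median over them.
    n_exclusion : int, default 10
        Maximum strongly-correlated pairs excluded (one per round) from
        the basis-variance system within each inference iteration.
    exclusion_threshold : float, default 0.1
        Exclusion stops once the strongest remaining |rho| falls at or
        below this value.
    random_state : int or numpy Generator, optional
        Seeds the Dirichlet resampling; fixed seed gives identical output.

    Attributes
    ----------
    correlation_ : ndarray of shape (n_genomes, n_genomes)
        Symmetric, unit-diagonal correlation matrix in [-1, 1].
    basis_variance_ : ndarray
        Basis variances from the final inference iteration.
    feature_names_in_ : ndarray of genome ids, when fit on a DataFrame.
    """

    def __init__(
        self,
        n_inference: int = 10,
        n_exclusion: int = 10,
        exclusion_threshold: float = 0.1,
        random_state=None,
    ):
        self.n_inference = n_inference
        self.n_exclusion = n_exclusion
        self.exclusion_threshold = exclusion_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a samples x genomes counts matrix."""
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2d samples x genomes matrix")
        n_samples, d = X.shape
        if d < 4:
            raise ValueError(f"need at least 4 genomes for a reliable basis solution, got {d}")
        prev = (X > 0).mean(axis=0)
        if (prev < 0.4).any():
            logger.warning(
                "%d genomes are below 40%% prevalence; consider filter_by_prevalence",
                int((prev < 0.4).sum()),
            )
        rng = np.random.default_rng(self.random_state)
        counts = X.T  # genomes x samples internally
        rhos = np.empty((self.n_inference, d, d))
        for it in range(self.n_inference):
            fractions = estimate_fractions(counts, rng)
            t = logratio_variance_matrix(fractions)
            rhos[it] = _single_inference(t, self.n_exclusion, self.exclusion_threshold)
        rho = np.median(rhos, axis=0)
        rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        self.correlation_ = rho
        self.basis_variance_ = solve_basis_variances(t)
        self.n_features_in_ = d
        return self


def sparcc_correlations(
    counts: AbundanceMatrix,
    n_inference: int = 10,
    n_exclusion: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int | None = None,
) -> CorrelationNetwork:
    """Run SparCC on a counts-mode abundance matrix."""
    if counts.mode != COUNTS:
        raise ValueError("sparcc expects a counts-mode matrix")
    est = SparCC(
        n_inference=n_inference,
        n_exclusion=n_exclusion,
        exclusion_threshold=exclusion_threshold,
        random_state=seed,
    ).fit(counts.data.T)
    rho = pd.DataFrame(est.correlation_, index=counts.genome_ids, columns=counts.genome_ids)
    return CorrelationNetwork(rho, n_inference=n_inference, seed=seed)
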