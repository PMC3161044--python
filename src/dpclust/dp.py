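"""Probabilistic core of the Dirichlet-process genotype mixture.

The model: individuals fall into an unknown number of populations, each
with its own allele-frequency vectors.  A Dirichlet process with
concentration ``alpha`` and a flat symmetric ``Dirichlet(lambda_l)`` base
measure over per-locus allele frequencies induces a Chinese-restaurant-
process (CRP) prior over partitions; allele frequencies are integrated
out analytically, leaving Dirichlet-multinomial predictive likelihoods
driven by per-cluster allele-copy counts ``y_jlh``.

Everything here is plain NumPy/SciPy and is deliberately independent of
the compiled MCMC kernels, so it can serve as the reference path for
exact enumeration on small problems.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

from .genotypes import MISSING
from .partition import canonical_labels


# ---------------------------------------------------------------------------
# CRP prior
# ---------------------------------------------------------------------------

def crp_weights(sizes, alpha: float) -> np.ndarray:
    """Sequential prior assignment probabilities for the next individual.

    Entry ``j < K`` is proportional to the cluster size |S_j|; the last
    entry, proportional to ``alpha``, is the probability of opening a new
    cluster.  With ``m`` individuals already placed the normaliser is
    ``m + alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    sizes = np.asarray(sizes, dtype=float)
    w = np.append(sizes, alpha)
    return w / w.sum()


def log_partition_prior(labels, alpha: float) -> float:
    """Log prior probability of a partition under the CRP.

    log[ alpha^K * Gamma(alpha)/Gamma(alpha+n) * prod_j Gamma(|S_j|) ],
    the product of the sequential weights over any insertion order.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    labels = canonical_labels(labels)
    sizes = np.bincount(labels)
    n = labels.size
    K = sizes.size
    return float(
        K * np.log(alpha) + gammaln(alpha) - gammaln(alpha + n) + gammaln(sizes).sum()
    )


# ---------------------------------------------------------------------------
# Dirichlet-multinomial predictive likelihoods
# ---------------------------------------------------------------------------

def _as_lambda(lam, L: int) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 0:
        lam = np.full(L, float(lam))
    if lam.shape != (L,):
        raise ValueError("lambda must be scalar or one value per locus")
    if np.any(lam <= 0):
        raise ValueError("lambda must be > 0")
    return lam


def log_predictive_individual(a1, a2, counts, totals, J, lam) -> float:
    """Log predictive probability of one individual's genotypes given the
    allele-copy counts of a (possibly empty) cluster.

    Per locus, with cluster counts ``y_h`` (total ``y``), the two allele
    copies h1, h2 have Dirichlet-multinomial probability

        het:  2 (y_h1+lam)(y_h2+lam) / (d (d+1)),  d = y + J*lam
        hom:     (y_h1+lam)(y_h1+lam+1) / (d (d+1))

    A single observed copy contributes ``(y_h+lam)/d``; a fully missing
    locus contributes 1.
    """
    a1 = np.asarray(a1, dtype=np.int64)
    a2 = np.asarray(a2, dtype=np.int64)
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    J = np.asarray(J, dtype=np.int64)
    L = a1.size
    lam = _as_lambda(lam, L)
    lp = 0.0
    for l in range(L):
        h1, h2 = a1[l], a2[l]
        if h1 == MISSING and h2 == MISSING:
            continue
        if h1 == MISSING:
            h1, h2 = h2, h1
        d = totals[l] + J[l] * lam[l]
        if h2 == MISSING:
            lp += np.log((counts[l, h1] + lam[l]) / d)
        elif h1 == h2:
            c = counts[l, h1] + lam[l]
            lp += np.log(c * (c + 1.0) / (d * (d + 1.0)))
        else:
            lp += np.log(
                2.0 * (counts[l, h1] + lam[l]) * (counts[l, h2] + lam[l]) / (d * (d + 1.0))
            )
    return float(lp)


def empty_counts(J) -> tuple[np.ndarray, np.ndarray]:
    """Zero allele-copy counts for a cluster over loci with J_l alleles."""
    J = np.asarray(J, dtype=np.int64)
    return np.zeros((J.size, int(J.max())), dtype=float), np.zeros(J.size, dtype=float)


def accumulate_counts(a1, a2, J) -> tuple[np.ndarray, np.ndarray]:
    """Allele-copy counts y_lh and totals y_l for a set of individuals."""
    a1 = np.atleast_2d(np.asarray(a1, dtype=np.int64))
    a2 = np.atleast_2d(np.asarray(a2, dtype=np.int64))
    J = np.asarray(J, dtype=np.int64)
    counts, totals = empty_counts(J)
    for l in range(J.size):
        col = np.concatenate([a1[:, l], a2[:, l]])
        col = col[col != MISSING]
        c = np.bincount(col, minlength=int(J.max()))
        counts[l] += c
        totals[l] += c.sum()
    return counts, totals


def log_marginal_set(a1, a2, J, lam) -> float:
    """Log marginal likelihood of a set of genotypes with allele
    frequencies integrated out under Dirichlet(lambda_l) priors.

    Closed form: per locus, Gamma(J*lam)/Gamma(J*lam + y) *
    prod_h Gamma(lam + y_h)/Gamma(lam), times 2 per heterozygous
    genotype.  Equals the sequential chain of
    :func:`log_predictive_individual` in any insertion order
    (exchangeability).
    """
    a1 = np.atleast_2d(np.asarray(a1, dtype=np.int64))
    a2 = np.atleast_2d(np.asarray(a2, dtype=np.int64))
    J = np.asarray(J, dtype=np.int64)
    L = J.size
    lam = _as_lambda(lam, L)
    counts, totals = accumulate_counts(a1, a2, J)
    lp = 0.0
    for l in range(L):
        lp += gammaln(J[l] * lam[l]) - gammaln(J[l] * lam[l] + totals[l])
        y = counts[l, : J[l]]
        lp += float(np.sum(gammaln(lam[l] + y) - gammaln(lam[l])))
    n_het = int(np.sum((a1 != a2) & (a1 != MISSING) & (a2 != MISSING)))
    return float(lp + n_het * np.log(2.0))


def log_marginal_partition(a1, a2, labels, J, lam) -> float:
    """Log marginal likelihood of all genotypes given a partition: the
    product of per-cluster set marginals."""
    labels = canonical_labels(labels)
    total = 0.0
    for j in range(labels.max() + 1):
        idx = np.flatnonzero(labels == j)
        total += log_marginal_set(a1[idx], a2[idx], J, lam)
    return total


# ---------------------------------------------------------------------------
# Prior distribution of the number of populations
# ---------------------------------------------------------------------------

def expected_k(n: int, alpha: float) -> float:
    """Closed-form prior mean of K: sum_{i=1..n} alpha/(alpha+i-1)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(alpha * (digamma(alpha + n) - digamma(alpha)))


def alpha_for_expected_k(n: int, k: float) -> float:
    """Concentration giving a prior expected number of clusters of ``k``."""
    if not 1.0 <= k <= n:
        raise ValueError("expected K must lie in [1, n]")
    if k == n:
        return np.inf
    return float(brentq(lambda a: expected_k(n, a) - k, 1e-10, 1e6))


def prior_k_distribution(
    n: int, alpha: float, draws: int = 10_000, seed=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Monte-Carlo prior distribution of K from sequential CRP assignment.

    Individuals are assigned one at a time; at step i a new cluster opens
    with probability alpha/(alpha+i-1) regardless of how the existing
    mass is spread over clusters, so K is the count of new-cluster
    events.  Returns (support, probabilities, Monte-Carlo mean).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    p_new = alpha / (alpha + np.arange(n))  # step i=1..n
    ks = (rng.random((draws, n)) < p_new).sum(axis=1)
    support, freq = np.unique(ks, return_counts=True)
    return support, freq / draws, float(ks.mean())
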