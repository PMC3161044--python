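"""scikit-learn style estimators over the genotype clustering samplers.

``X`` is an integer array of shape (n_individuals, 2 * n_loci) with the
two allele codes of each locus in adjacent columns (dense 0-based codes,
``missing_value`` for unobserved copies), or a
:class:`~dpclust.genotypes.GenotypeTable`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .genotypes import MISSING, GenotypeTable
from .dp import alpha_for_expected_k
from .fixed_k import run_fixed_k
from .mcmc import run_mcmc
from .summaries import coassignment_matrix, mean_partition, posterior_k


def _to_arrays(X, missing_value):
    if isinstance(X, GenotypeTable):
        a1, a2 = X.allele_arrays()
        return a1, a2, X.n_alleles
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] % 2:
        raise ValueError("X must be (n_individuals, 2 * n_loci)")
    X = X.astype(np.int64)
    X = np.where(X == missing_value, MISSING, X)
    a1 = np.ascontiguousarray(X[:, 0::2])
    a2 = np.ascontiguousarray(X[:, 1::2])
    J = np.maximum(np.maximum(a1.max(axis=0), a2.max(axis=0)), 0) + 1
    return a1, a2, J


class DirichletProcessClustering(ClusterMixin, BaseEstimator):
    """Bayesian clustering of multilocus genotypes under a Dirichlet-
    process prior.

    The number of clusters and the assignment of individuals are
    inferred jointly: a Chinese-restaurant-process prior with
    concentration ``alpha`` over partitions, Dirichlet(lambda) priors
    over per-cluster allele frequencies (integrated out analytically),
    and an MCMC chain mixing sequentially-allocated merge-split moves
    with Gibbs scans.  The fitted labels are the mean partition of the
    posterior sample.

    Parameters
    ----------
    alpha : float, default 1.0
        DP concentration; larger values favour more clusters a priori.
        Ignored when ``expected_k`` is given.
    expected_k : float, optional
        If set, ``alpha`` is solved so the prior expected number of
        clusters equals this value.
    lam : float, array, or "1/J", default 1.0
        Allele-frequency hyperparameter per locus (initial value when
        inferred).  "1/J" sets lambda_l to the reciprocal of the
        observed allele count.
    lambda_mode : {"fixed", "single", "unique"}, default "fixed"
        Whether lambda is held fixed, inferred as one shared value, or
        inferred per locus (uniform prior on (0, 10], Metropolis
        updates).
    iterations, burn_in, thin : MCMC schedule; ``burn_in`` defaults to
        half the iterations; thinning keeps every ``thin``-th partition.
    sams_per_cycle, gibbs_per_cycle : move schedule, default 4 merge-
        split iterations per Gibbs scan.
    delta : float, default 0.02
        Standard deviation of the normal lambda proposal.
    init : {"single", "crp"} or label vector, default "single"
        Initial partition (all individuals in one cluster by default).
    missing_value : int, default -1
        Code for missing allele copies in array input.
    random_state : int, optional

    Attributes
    ----------
    labels_ : mean-partition cluster labels (canonical form)
    n_clusters_ : number of clusters in the mean partition
    mean_partition_distance_ : average normalised distance between the
        mean partition and the sampled partitions
    trace_ : the full :class:`~dpclust.mcmc.MCMCTrace`
    posterior_k_, mean_k_ : posterior histogram and mean of K
    lambda_ : posterior mean of lambda per locus (inferred modes)
    """

    def __init__(self, alpha=1.0, expected_k=None, lam=1.0, lambda_mode="fixed",
                 iterations=20_000, burn_in=None, thin=10, sams_per_cycle=4,
                 gibbs_per_cycle=1, delta=0.02, init="single", missing_value=-1,
                 random_state=None):
        self.alpha = alpha
        self.expected_k = expected_k
        self.lam = lam
        self.lambda_mode = lambda_mode
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.sams_per_cycle = sams_per_cycle
        self.gibbs_per_cycle = gibbs_per_cycle
        self.delta = delta
        self.init = init
        self.missing_value = missing_value
        self.random_state = random_state

    def fit(self, X, y=None):
        a1, a2, J = _to_arrays(X, self.missing_value)
        alpha = self.alpha
        if self.expected_k is not None:
            alpha = alpha_for_expected_k(a1.shape[0], self.expected_k)
        self.alpha_ = float(alpha)
        self.trace_ = run_mcmc(
            (a1, a2, J), alpha=alpha, lam=self.lam, lambda_mode=self.lambda_mode,
            iterations=self.iterations, burn_in=self.burn_in, thin=self.thin,
            sams_per_cycle=self.sams_per_cycle, gibbs_per_cycle=self.gibbs_per_cycle,
            delta=self.delta, init=self.init, seed=self.random_state)
        labels, D = mean_partition(self.trace_.partitions)
        self.labels_ = labels
        self.n_clusters_ = int(labels.max()) + 1
        self.mean_partition_distance_ = D / (self.trace_.n_samples * a1.shape[0])
        self.posterior_k_, self.mean_k_ = posterior_k(self.trace_.partitions)
        if self.trace_.lambdas is not None:
            self.lambda_ = self.trace_.lambdas.mean(axis=0)
        return self

    def coassignment_matrix(self):
        return coassignment_matrix(self.trace_.partitions)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class FixedKClustering(ClusterMixin, BaseEstimator):
    """Fixed-K no-admixture Gibbs sampler (STRUCTURE-like baseline).

    ``model="uncorrelated"`` places independent flat Dirichlet priors on
    each cluster's allele frequencies; ``model="correlated"`` ties them
    to inferred ancestral frequencies through per-cluster drift
    parameters F_j with a U(0,1) prior.  The first half of burn-in uses
    an admixture-style warm-up that assigns allele copies independently,
    which keeps all K clusters populated.

    Attributes: ``labels_`` (max-posterior-probability assignment),
    ``assignment_proba_`` (n x K aligned posterior assignment
    probabilities), ``trace_``.
    """

    def __init__(self, n_clusters=2, model="uncorrelated", iterations=20_000,
                 burn_in=None, thin=10, warmup=True, missing_value=-1,
                 random_state=None):
        self.n_clusters = n_clusters
        self.model = model
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.warmup = warmup
        self.missing_value = missing_value
        self.random_state = random_state

    def fit(self, X, y=None):
        a1, a2, J = _to_arrays(X, self.missing_value)
        model = {"uncorrelated": "fum", "correlated": "fcm"}.get(self.model, self.model)
        self.trace_ = run_fixed_k(
            (a1, a2, J), self.n_clusters, model, iterations=self.iterations,
            burn_in=self.burn_in, thin=self.thin, warmup=self.warmup,
            seed=self.random_state)
        self.assignment_proba_ = self.trace_.assignment_proba
        self.labels_ = self.trace_.map_partition
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
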