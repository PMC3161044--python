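"""Fixed-K Gibbs samplers used as comparison baselines.

Both samplers assign individuals to a fixed number of clusters K with
equal prior weight 1/K per cluster and explicitly sample the allele
frequencies that the DP sampler integrates out:

* FUM (uncorrelated model): per-cluster allele frequencies get
  independent flat Dirichlet(1) priors, so the conditional update is
  Dirichlet(y + 1).
* FCM (correlated model): cluster frequencies are tied to a virtual
  ancestral frequency vector Pa through per-cluster drift parameters
  F_j — the conditional update is Dirichlet(y + Pa * f_j) with
  f_j = (1 - F_j)/F_j; Pa and F_j are updated by Metropolis-Hastings
  (flat Dirichlet prior on Pa, U(0,1) prior on F_j).

During the first half of burn-in the chain runs an admixture-style
warm-up: each of an individual's allele copies may be assigned to a
different cluster under flat per-individual mixture weights.  This keeps
every cluster populated early on; afterwards strict no-admixture label
sweeps take over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable
from .partition import canonical_labels

_TINY = 1e-300


@dataclass
class FixedKState:
    """Labels, per-cluster allele frequencies, and (correlated model)
    ancestral frequencies and drift parameters."""

    labels: np.ndarray            # (n,)
    P: np.ndarray                 # (K, L, Hmax) frequencies (0 beyond J_l)
    pa: np.ndarray | None = None  # (L, Hmax) ancestral frequencies
    F: np.ndarray | None = None   # (K,) drift parameters in (0,1)

    @property
    def K(self) -> int:
        return self.P.shape[0]


def _valid_mask(J, Hmax) -> np.ndarray:
    return np.arange(Hmax)[None, :] < np.asarray(J)[:, None]  # (L, Hmax)


def _dirichlet_rows(shape_param, rng) -> np.ndarray:
    """Dirichlet draws along the last axis from a (possibly zero-padded)
    shape-parameter array; zero shapes yield exact zeros."""
    g = rng.standard_gamma(shape_param)
    tot = g.sum(axis=-1, keepdims=True)
    return g / np.where(tot > 0, tot, 1.0)


def init_state(a1, a2, J, K, model, rng) -> FixedKState:
    n, L = a1.shape
    Hmax = int(np.max(J))
    valid = _valid_mask(J, Hmax)
    labels = rng.integers(0, K, size=n)
    y = _count_alleles(a1, a2, labels, K, L, Hmax)
    state = FixedKState(labels, np.zeros((K, L, Hmax)))
    if model == "fcm":
        overall = y.sum(axis=0) + valid  # observed counts + flat prior
        state.pa = _dirichlet_rows(np.where(valid, overall, 0.0), rng)
        state.F = rng.uniform(0.05, 0.95, size=K)
        _resample_frequencies(state, y, valid, rng)
    else:
        _resample_frequencies(state, y, valid, rng)
    return state


def _genotype_copies(a1, a2, Hmax) -> np.ndarray:
    """(n, L, Hmax) allele-copy counts per individual (0/1/2; missing
    copies contribute nothing).  Precomputed once per run: it turns the
    label likelihood into a matrix product and cluster counts into row
    sums."""
    n, L = a1.shape
    G = np.zeros((n, L, Hmax))
    lidx = np.broadcast_to(np.arange(L), a1.shape)
    iidx = np.broadcast_to(np.arange(n)[:, None], a1.shape)
    for a in (a1, a2):
        ok = a != MISSING
        np.add.at(G, (iidx[ok], lidx[ok], a[ok]), 1.0)
    return G


def _count_alleles(a1, a2, labels, K, L, Hmax, copies=None) -> np.ndarray:
    if copies is None:
        copies = _genotype_copies(a1, a2, Hmax)
    y = np.empty((K, L, Hmax))
    for j in range(K):
        y[j] = copies[labels == j].sum(axis=0)
    return y


def _resample_frequencies(state: FixedKState, y, valid, rng) -> None:
    if state.pa is None:
        shape = y + valid[None, :, :]
    else:
        f = (1.0 - state.F) / state.F
        shape = y + state.pa[None, :, :] * f[:, None, None]
        shape = np.where(valid[None, :, :], np.maximum(shape, 1e-6), 0.0)
    state.P = _dirichlet_rows(np.where(valid[None, :, :], shape, 0.0), rng)


def _label_loglik(a1, a2, P, copies=None) -> np.ndarray:
    """(n, K) log likelihood of each individual under each cluster's
    frequencies (the 2^het factor is constant across clusters)."""
    if copies is None:
        copies = _genotype_copies(a1, a2, P.shape[2])
    # slots beyond J_l have zero copies everywhere, so their clipped log
    # contributes nothing to the product
    logP = np.log(np.maximum(P, _TINY))            # (K, L, H)
    K = P.shape[0]
    return copies.reshape(copies.shape[0], -1) @ logP.reshape(K, -1).T


def _resample_labels(a1, a2, state: FixedKState, rng, copies=None) -> None:
    ll = _label_loglik(a1, a2, state.P, copies)
    state.labels = np.argmax(ll + rng.gumbel(size=ll.shape), axis=1)


def _log_dirichlet_pdf(x, alpha, valid) -> np.ndarray:
    """Row-wise log Dirichlet density over the valid allele slots."""
    a = np.where(valid, alpha, 1.0)
    lx = np.log(np.maximum(x, _TINY))
    terms = np.where(valid, (a - 1.0) * lx - gammaln(a), 0.0)
    return gammaln(np.where(valid, alpha, 0.0).sum(axis=-1)) + terms.sum(axis=-1)


def _update_pa(state: FixedKState, valid, rng, concentration=200.0) -> None:
    """Per-locus MH update of the ancestral frequencies with a Dirichlet
    neighbourhood proposal (flat Dirichlet prior)."""
    pa = state.pa
    shape = np.where(valid, concentration * pa + 1e-3, 0.0)
    prop = _dirichlet_rows(shape, rng)
    prop = np.where(valid, np.maximum(prop, 1e-9), 0.0)
    prop /= prop.sum(axis=-1, keepdims=True)
    f = (1.0 - state.F) / state.F
    cur_t = np.zeros(pa.shape[0])
    new_t = np.zeros(pa.shape[0])
    for j in range(state.K):
        cur_t += _log_dirichlet_pdf(state.P[j], f[j] * pa, valid)
        new_t += _log_dirichlet_pdf(state.P[j], f[j] * prop, valid)
    shape_rev = np.where(valid, concentration * prop + 1e-3, 0.0)
    log_q_fwd = _log_dirichlet_pdf(prop, shape, valid)
    log_q_rev = _log_dirichlet_pdf(pa, shape_rev, valid)
    log_acc = new_t - cur_t + log_q_rev - log_q_fwd
    accept = np.log(rng.random(pa.shape[0])) < log_acc
    state.pa = np.where(accept[:, None], prop, pa)


def _update_F(state: FixedKState, valid, rng, proposal_sd=0.3) -> None:
    """Per-cluster MH update of the drift parameter on the logit scale
    (uniform prior on (0,1); Jacobian F(1-F) enters the ratio)."""
    for j in range(state.K):
        Fj = state.F[j]
        z = np.log(Fj / (1 - Fj)) + proposal_sd * rng.standard_normal()
        Fp = 1.0 / (1.0 + np.exp(-z))
        if not 0.0 < Fp < 1.0:
            continue
        f_cur = (1 - Fj) / Fj
        f_new = (1 - Fp) / Fp
        cur = _log_dirichlet_pdf(state.P[j], f_cur * state.pa, valid).sum()
        new = _log_dirichlet_pdf(state.P[j], f_new * state.pa, valid).sum()
        log_acc = new - cur + np.log(Fp * (1 - Fp)) - np.log(Fj * (1 - Fj))
        if np.log(rng.random()) < log_acc:
            state.F[j] = Fp


def fum_sweep(state: FixedKState, a1, a2, J, rng, copies=None) -> FixedKState:
    """One no-admixture sweep of the uncorrelated model: resample labels
    given frequencies, then frequencies from Dirichlet(y + 1)."""
    Hmax = state.P.shape[2]
    valid = _valid_mask(J, Hmax)
    _resample_labels(a1, a2, state, rng, copies)
    y = _count_alleles(a1, a2, state.labels, state.K, a1.shape[1], Hmax, copies)
    _resample_frequencies(state, y, valid, rng)
    return state


def fcm_sweep(state: FixedKState, a1, a2, J, rng, copies=None) -> FixedKState:
    """One no-admixture sweep of the correlated model: labels, then
    P_j ~ Dirichlet(y_j + Pa f_j), then MH updates of Pa and F_j."""
    Hmax = state.P.shape[2]
    valid = _valid_mask(J, Hmax)
    _resample_labels(a1, a2, state, rng, copies)
    y = _count_alleles(a1, a2, state.labels, state.K, a1.shape[1], Hmax, copies)
    _resample_frequencies(state, y, valid, rng)
    _update_pa(state, valid, rng)
    _update_F(state, valid, rng)
    return state


def _admixture_warmup_sweep(state: FixedKState, a1, a2, J, rng) -> None:
    """Admixture-style warm-up sweep: flat per-individual mixture
    weights, independent cluster assignment of every allele copy, then
    the usual frequency (and Pa/F) updates."""
    n, L = a1.shape
    K = state.K
    Hmax = state.P.shape[2]
    valid = _valid_mask(J, Hmax)
    w = _dirichlet_rows(np.ones((n, K)), rng)  # flat Dirichlet weights
    y = np.zeros((K, L, Hmax))
    logw = np.log(np.maximum(w, _TINY))
    logP = np.log(np.maximum(state.P, _TINY))
    a = np.concatenate([a1, a2], axis=1)                       # (n, 2L)
    lidx = np.tile(np.arange(L), 2)
    ok = a != MISSING
    lp = logP[:, lidx[None, :], np.where(ok, a, 0)]            # (K, n, 2L)
    lp = lp + logw.T[:, :, None]
    z = np.argmax(lp + rng.gumbel(size=lp.shape), axis=0)      # (n, 2L)
    flat = (z[ok] * L + np.broadcast_to(lidx, a.shape)[ok]) * Hmax + a[ok]
    y += np.bincount(flat, minlength=K * L * Hmax).reshape(K, L, Hmax)
    _resample_frequencies(state, y, valid, rng)
    if state.pa is not None:
        _update_pa(state, valid, rng)
        _update_F(state, valid, rng)


@dataclass
class FixedKTrace:
    partitions: np.ndarray           # (samples, n) canonical labels
    assignment_proba: np.ndarray     # (n, K) aligned posterior assignment probabilities
    map_partition: np.ndarray        # argmax-probability labels (canonical)
    iterations: int
    burn_in: int
    thin: int


def _align(reference: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """Permute cluster ids of ``labels`` to best match the reference
    labelling (maximum shared membership, Hungarian)."""
    C = np.zeros((K, K))
    np.add.at(C, (reference, labels), 1.0)
    r, c = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=np.int64)
    perm[c] = r
    return perm[labels]


def run_fixed_k(
    table,
    K: int,
    model: str = "fum",
    *,
    iterations: int = 20_000,
    burn_in: int | None = None,
    thin: int = 10,
    warmup: bool = True,
    seed=None,
) -> FixedKTrace:
    """Run the fixed-K sampler and return aligned assignment
    probabilities plus the max-probability partition.

    The first half of burn-in runs admixture-style warm-up sweeps (when
    ``warmup``), the remainder strict no-admixture sweeps.  Sampled
    labelings are aligned to a running reference before averaging, so
    label switching cannot blur the probabilities.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if model not in ("fum", "fcm"):
        raise ValueError("model must be 'fum' or 'fcm'")
    if burn_in is None:
        burn_in = iterations // 2
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    rng = np.random.default_rng(seed)
    if isinstance(table, GenotypeTable):
        a1, a2 = table.allele_arrays()
        J = table.n_alleles
    else:
        a1, a2, J = table
    a1 = np.asarray(a1, dtype=np.int64)
    a2 = np.asarray(a2, dtype=np.int64)
    J = np.asarray(J, dtype=np.int64)
    n = a1.shape[0]
    state = init_state(a1, a2, J, K, model, rng)
    sweep = fcm_sweep if model == "fcm" else fum_sweep
    warm_end = burn_in // 2 if warmup else 0
    copies = _genotype_copies(a1, a2, int(np.max(J)))

    n_samples = (iterations - burn_in) // thin
    parts = np.empty((n_samples, n), dtype=np.int64)
    counts = np.zeros((n, K))
    reference = None
    s = 0
    for t in range(1, iterations + 1):
        if t <= warm_end:
            _admixture_warmup_sweep(state, a1, a2, J, rng)
            continue
        sweep(state, a1, a2, J, rng, copies)
        if t > burn_in and (t - burn_in) % thin == 0:
            lab = state.labels.astype(np.int64)
            if reference is None:
                reference = lab.copy()
            aligned = _align(reference, lab, K)
            counts[np.arange(n), aligned] += 1.0
            parts[s] = canonical_labels(lab)
            s += 1
    proba = counts / max(s, 1)
    map_part = canonical_labels(np.argmax(proba, axis=1))
    return FixedKTrace(parts[:s], proba, map_part, iterations, burn_in, thin)
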