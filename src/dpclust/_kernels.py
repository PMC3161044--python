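"""Compiled inner loops for the partition MCMC and summaries.

All kernels operate on a flat state: allele slot arrays ``a1``/``a2``
(n, L) with -1 for missing, per-locus allele counts ``J``, per-locus
Dirichlet hyperparameters ``lam``, a label vector, per-cluster sizes and
allele-copy count arrays ``y`` (Kcap, L, Hmax) / ``ytot`` (Kcap, L).

Cluster slots are kept compact in ``0..K-1``; every slot at index >= K
is all-zero and doubles as scratch for proposal clusters (capacity is
n + 2 rows).  Randomness comes from numba's internal np.random state,
seeded once per run via :func:`seed_kernels`.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernels(seed):
    np.random.seed(seed)


@njit(cache=True)
def _log_pred(i, j, a1, a2, y, ytot, J, lam):
    """Log Dirichlet-multinomial predictive of individual i's genotypes
    under the counts of cluster slot j (two-copy/one-copy/absent per
    locus, with the factor 2 for heterozygotes)."""
    L = a1.shape[1]
    lp = 0.0
    for l in range(L):
        h1 = a1[i, l]
        h2 = a2[i, l]
        if h1 < 0 and h2 < 0:
            continue
        if h1 < 0:
            h1, h2 = h2, h1
        lam_l = lam[l]
        d = ytot[j, l] + J[l] * lam_l
        if h2 < 0:
            lp += math.log((y[j, l, h1] + lam_l) / d)
        elif h1 == h2:
            c = y[j, l, h1] + lam_l
            lp += math.log(c * (c + 1.0) / (d * (d + 1.0)))
        else:
            lp += math.log(
                2.0 * (y[j, l, h1] + lam_l) * (y[j, l, h2] + lam_l) / (d * (d + 1.0))
            )
    return lp


@njit(cache=True)
def _move_counts(i, j, sign, a1, a2, y, ytot, sizes):
    L = a1.shape[1]
    for l in range(L):
        h1 = a1[i, l]
        if h1 >= 0:
            y[j, l, h1] += sign
            ytot[j, l] += sign
        h2 = a2[i, l]
        if h2 >= 0:
            y[j, l, h2] += sign
            ytot[j, l] += sign
    sizes[j] += sign


@njit(cache=True)
def _zero_slot(j, y, ytot, sizes):
    y[j, :, :] = 0
    ytot[j, :] = 0
    sizes[j] = 0


@njit(cache=True)
def _drop_cluster(j, K, labels, sizes, y, ytot):
    """Remove empty cluster slot j, moving slot K-1 into it."""
    last = K - 1
    if j != last:
        for t in range(labels.shape[0]):
            if labels[t] == last:
                labels[t] = j
        sizes[j] = sizes[last]
        y[j, :, :] = y[last, :, :]
        ytot[j, :] = ytot[last, :]
    _zero_slot(last, y, ytot, sizes)


@njit(cache=True)
def _sample_categorical_log(logw, m):
    mx = logw[0]
    for k in range(1, m):
        if logw[k] > mx:
            mx = logw[k]
    tot = 0.0
    for k in range(m):
        logw[k] = math.exp(logw[k] - mx)
        tot += logw[k]
    u = np.random.random() * tot
    acc = 0.0
    for k in range(m):
        acc += logw[k]
        if u <= acc:
            return k
    return m - 1


@njit(cache=True)
def gibbs_scan(a1, a2, J, lam, alpha, labels, sizes, y, ytot, K):
    """One Gibbs scan: remove each individual in index order and
    reassign it to existing clusters with weight |S_j| * predictive or a
    new cluster with weight alpha * predictive.  Returns the new K."""
    n = a1.shape[0]
    logw = np.empty(n + 1)
    for i in range(n):
        j0 = labels[i]
        _move_counts(i, j0, -1, a1, a2, y, ytot, sizes)
        if sizes[j0] == 0:
            _drop_cluster(j0, K, labels, sizes, y, ytot)
            K -= 1
        for j in range(K):
            logw[j] = math.log(float(sizes[j])) + _log_pred(i, j, a1, a2, y, ytot, J, lam)
        logw[K] = math.log(alpha) + _log_pred(i, K, a1, a2, y, ytot, J, lam)
        j = _sample_categorical_log(logw, K + 1)
        if j == K:
            K += 1
        labels[i] = j
        _move_counts(i, j, 1, a1, a2, y, ytot, sizes)
    return K


@njit(cache=True)
def _log_dm(j, y, ytot, J, lam):
    """Log Dirichlet-multinomial marginal of the allele counts in slot j
    (heterozygote 2^det factors omitted: they cancel in all ratios)."""
    L = J.shape[0]
    s = 0.0
    for l in range(L):
        if ytot[j, l] == 0:
            continue
        jl = J[l] * lam[l]
        s += math.lgamma(jl) - math.lgamma(jl + ytot[j, l])
        for h in range(J[l]):
            if y[j, l, h] > 0:
                s += math.lgamma(lam[l] + y[j, l, h]) - math.lgamma(lam[l])
    return s


@njit(cache=True)
def _log_dm_pair(j1, j2, y, ytot, J, lam):
    """Log marginal of the pooled counts of slots j1 and j2."""
    L = J.shape[0]
    s = 0.0
    for l in range(L):
        tot = ytot[j1, l] + ytot[j2, l]
        if tot == 0:
            continue
        jl = J[l] * lam[l]
        s += math.lgamma(jl) - math.lgamma(jl + tot)
        for h in range(J[l]):
            c = y[j1, l, h] + y[j2, l, h]
            if c > 0:
                s += math.lgamma(lam[l] + c) - math.lgamma(lam[l])
    return s


@njit(cache=True)
def sams_move(a1, a2, J, lam, alpha, labels, sizes, y, ytot, K):
    """One sequentially-allocated merge-split move.

    Two distinct individuals are drawn uniformly.  If they share a
    cluster, a split is proposed by sequentially allocating the other
    members (random order) to the two seeded singletons with probability
    proportional to cluster size times predictive; otherwise the merge
    of their two clusters is proposed, with the reverse split replayed
    in a random order to obtain the proposal density.  Metropolis-
    Hastings acceptance uses the prior ratio from the CRP partition
    prior and the marginal-likelihood ratio.

    Returns (K, move_type, accepted) with move_type 0=split, 1=merge.
    """
    n = a1.shape[0]
    i = np.random.randint(n)
    jj = np.random.randint(n - 1)
    if jj >= i:
        jj += 1
    ci = labels[i]
    cj = labels[jj]
    A = K      # scratch slot for the cluster seeded by i
    B = K + 1  # scratch slot for the cluster seeded by j
    if ci == cj:
        # ---- split proposal -------------------------------------------
        _move_counts(i, A, 1, a1, a2, y, ytot, sizes)
        _move_counts(jj, B, 1, a1, a2, y, ytot, sizes)
        mem = np.empty(n, np.int64)
        m = 0
        for t in range(n):
            if labels[t] == ci and t != i and t != jj:
                mem[m] = t
                m += 1
        for t in range(m - 1, 0, -1):
            u = np.random.randint(t + 1)
            tmp = mem[t]
            mem[t] = mem[u]
            mem[u] = tmp
        to_b = np.zeros(n, np.uint8)
        logq = 0.0
        for t in range(m):
            k = mem[t]
            la = math.log(float(sizes[A])) + _log_pred(k, A, a1, a2, y, ytot, J, lam)
            lb = math.log(float(sizes[B])) + _log_pred(k, B, a1, a2, y, ytot, J, lam)
            mx = la if la > lb else lb
            pa = math.exp(la - mx)
            pb = math.exp(lb - mx)
            p = pa / (pa + pb)
            if np.random.random() < p:
                logq += math.log(p)
                _move_counts(k, A, 1, a1, a2, y, ytot, sizes)
            else:
                logq += math.log(1.0 - p)
                _move_counts(k, B, 1, a1, a2, y, ytot, sizes)
                to_b[k] = 1
        log_lik = (
            _log_dm(A, y, ytot, J, lam)
            + _log_dm(B, y, ytot, J, lam)
            - _log_dm(ci, y, ytot, J, lam)
        )
        log_prior = (
            math.log(alpha)
            + math.lgamma(float(sizes[A]))
            + math.lgamma(float(sizes[B]))
            - math.lgamma(float(sizes[ci]))
        )
        log_acc = log_lik + log_prior - logq  # q(old|new) = 1 for the merge back
        accepted = math.log(np.random.random()) < log_acc
        if accepted:
            # slot A replaces ci; slot B becomes new cluster K
            sizes[ci] = sizes[A]
            y[ci, :, :] = y[A, :, :]
            ytot[ci, :] = ytot[A, :]
            _zero_slot(A, y, ytot, sizes)
            # B currently at K+1, move into K (== A slot just zeroed)
            sizes[K] = sizes[B]
            y[K, :, :] = y[B, :, :]
            ytot[K, :] = ytot[B, :]
            _zero_slot(B, y, ytot, sizes)
            for t in range(m):
                k = mem[t]
                if to_b[k] == 1:
                    labels[k] = K
            labels[jj] = K
            K += 1
        else:
            _zero_slot(A, y, ytot, sizes)
            _zero_slot(B, y, ytot, sizes)
        return K, 0, accepted
    else:
        # ---- merge proposal -------------------------------------------
        _move_counts(i, A, 1, a1, a2, y, ytot, sizes)
        _move_counts(jj, B, 1, a1, a2, y, ytot, sizes)
        mem = np.empty(n, np.int64)
        m = 0
        for t in range(n):
            if (labels[t] == ci or labels[t] == cj) and t != i and t != jj:
                mem[m] = t
                m += 1
        for t in range(m - 1, 0, -1):
            u = np.random.randint(t + 1)
            tmp = mem[t]
            mem[t] = mem[u]
            mem[u] = tmp
        # replay the reverse split of the merged cluster into the two
        # original subsets to obtain q(old | merged)
        logq = 0.0
        for t in range(m):
            k = mem[t]
            la = math.log(float(sizes[A])) + _log_pred(k, A, a1, a2, y, ytot, J, lam)
            lb = math.log(float(sizes[B])) + _log_pred(k, B, a1, a2, y, ytot, J, lam)
            mx = la if la > lb else lb
            pa = math.exp(la - mx)
            pb = math.exp(lb - mx)
            p = pa / (pa + pb)
            if labels[k] == ci:
                logq += math.log(p)
                _move_counts(k, A, 1, a1, a2, y, ytot, sizes)
            else:
                logq += math.log(1.0 - p)
                _move_counts(k, B, 1, a1, a2, y, ytot, sizes)
        log_lik = (
            _log_dm_pair(ci, cj, y, ytot, J, lam)
            - _log_dm(ci, y, ytot, J, lam)
            - _log_dm(cj, y, ytot, J, lam)
        )
        log_prior = (
            math.lgamma(float(sizes[ci] + sizes[cj]))
            - math.log(alpha)
            - math.lgamma(float(sizes[ci]))
            - math.lgamma(float(sizes[cj]))
        )
        log_acc = log_lik + log_prior + logq  # q(new|old) = 1
        accepted = math.log(np.random.random()) < log_acc
        _zero_slot(A, y, ytot, sizes)
        _zero_slot(B, y, ytot, sizes)
        if accepted:
            for t in range(n):
                if labels[t] == cj:
                    labels[t] = ci
            sizes[ci] += sizes[cj]
            y[ci, :, :] += y[cj, :, :]
            ytot[ci, :] += ytot[cj, :]
            sizes[cj] = 0
            y[cj, :, :] = 0
            ytot[cj, :] = 0
            _drop_cluster(cj, K, labels, sizes, y, ytot)
            K -= 1
        return K, 1, accepted


@njit(cache=True)
def _log_dm_locus(j, l, y, ytot, J, lam_l):
    if ytot[j, l] == 0:
        return 0.0
    jl = J[l] * lam_l
    s = math.lgamma(jl) - math.lgamma(jl + ytot[j, l])
    for h in range(J[l]):
        if y[j, l, h] > 0:
            s += math.lgamma(lam_l + y[j, l, h]) - math.lgamma(lam_l)
    return s


@njit(cache=True)
def lambda_update_unique(J, lam, delta, upper, y, ytot, K):
    """One Metropolis-Hastings update of lambda_l at every locus.

    The prior is U(0, upper) and the normal proposal is symmetric, so
    the acceptance ratio is the marginal-likelihood ratio at that locus;
    proposals outside the support are rejected outright.  Returns the
    number of accepted updates."""
    L = J.shape[0]
    acc = 0
    for l in range(L):
        prop = lam[l] + delta * np.random.normal()
        if prop <= 0.0 or prop > upper:
            continue
        d = 0.0
        for j in range(K):
            d += _log_dm_locus(j, l, y, ytot, J, prop) - _log_dm_locus(
                j, l, y, ytot, J, lam[l]
            )
        if math.log(np.random.random()) < d:
            lam[l] = prop
            acc += 1
    return acc


@njit(cache=True)
def lambda_update_single(J, lam, delta, upper, y, ytot, K):
    """One MH update of a single lambda shared by all loci (lam is the
    full per-locus vector, kept constant across entries)."""
    L = J.shape[0]
    prop = lam[0] + delta * np.random.normal()
    if prop <= 0.0 or prop > upper:
        return 0
    d = 0.0
    for l in range(L):
        for j in range(K):
            d += _log_dm_locus(j, l, y, ytot, J, prop) - _log_dm_locus(
                j, l, y, ytot, J, lam[l]
            )
    if math.log(np.random.random()) < d:
        for l in range(L):
            lam[l] = prop
        return 1
    return 0


# ---------------------------------------------------------------------------
# partition-distance helpers (used by the mean-partition search)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _max_overlap(C, K1, K2, dp):
    """Maximum-weight matching of an overlap matrix by bitmask dynamic
    programming over the smaller side (exact; requires min(K1,K2) <= ~10)."""
    if K2 <= K1:
        R, Cn = K1, K2
        transpose = False
    else:
        R, Cn = K2, K1
        transpose = True
    full = 1 << Cn
    for mask in range(full):
        dp[mask] = 0.0
    for r in range(R):
        for mask in range(full - 1, -1, -1):
            best = dp[mask]
            for c in range(Cn):
                bit = 1 << c
                if mask & bit:
                    w = C[c, r] if transpose else C[r, c]
                    cand = dp[mask ^ bit] + w
                    if cand > best:
                        best = cand
            dp[mask] = best
    return dp[full - 1]


@njit(cache=True)
def _distance_to_samples(u, K_u, samples, samp_k, counts, weights, C, dp):
    """Sum over stored samples of multiplicity-weighted partition
    distance between candidate labels u and each sample."""
    n = u.shape[0]
    total_w = 0.0
    for i in range(n):
        total_w += weights[i]
    D = 0.0
    for s in range(samples.shape[0]):
        K_s = samp_k[s]
        for r in range(K_u):
            for c in range(K_s):
                C[r, c] = 0.0
        for i in range(n):
            C[u[i], samples[s, i]] += weights[i]
        ov = _max_overlap(C, K_u, K_s, dp)
        D += counts[s] * (total_w - ov)
    return D


@njit(cache=True)
def _canonicalize(u):
    n = u.shape[0]
    mapping = np.full(n + 1, -1, np.int64)
    nxt = 0
    for i in range(n):
        if mapping[u[i]] < 0:
            mapping[u[i]] = nxt
            nxt += 1
        u[i] = mapping[u[i]]
    return nxt


@njit(cache=True)
def mean_partition_greedy(u0, samples, samp_k, counts, weights):
    """Greedy coordinate-descent for the mean partition: sweep the
    individuals in index order, move each to every existing cluster and
    to a new one, keep strict improvements, repeat until no decrease.

    Returns (labels, K, total distance D)."""
    n = u0.shape[0]
    u = u0.copy()
    K_u = _canonicalize(u)
    kcap = n + 2
    C = np.zeros((kcap, kcap))
    dp = np.zeros(1 << 11)
    D = _distance_to_samples(u, K_u, samples, samp_k, counts, weights, C, dp)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            base = u[i]
            best = D
            bestj = -1
            for j in range(K_u + 1):
                if j == base:
                    continue
                u[i] = j
                v = u.copy()
                K_v = _canonicalize(v)
                Dp = _distance_to_samples(v, K_v, samples, samp_k, counts, weights, C, dp)
                if Dp < best:
                    best = Dp
                    bestj = j
            u[i] = base
            if bestj >= 0:
                u[i] = bestj
                K_u = _canonicalize(u)
                D = best
                improved = True
    return u, K_u, D
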