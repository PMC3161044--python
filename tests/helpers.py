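"""Independent oracles used by the test suite.

Everything here is deliberately simple and brute-force: set-partition
enumeration, minimal-removal partition distance by subset search,
exhaustive matching search, and exact posteriors over all partitions.
These never share code with the compiled samplers they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from dpclust import canonical_labels, log_marginal_partition, log_partition_prior


def set_partitions(n: int):
    """All set partitions of {0..n-1} as restricted-growth label tuples."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([0], 0)


def brute_force_distance(l1, l2) -> int:
    """Minimal number of individuals to remove from both partitions so
    the restrictions are identical — literal subset search (n <= ~10)."""
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)
    n = l1.size
    for k in range(n + 1):
        for keep in itertools.combinations(range(n), n - k):
            keep = list(keep)
            if tuple(canonical_labels(l1[keep])) == tuple(canonical_labels(l2[keep])):
                return k
    return n


def brute_force_max_overlap(l1, l2) -> int:
    """Maximum total overlap over all injective cluster matchings,
    enumerated directly (K <= ~6)."""
    l1 = canonical_labels(l1)
    l2 = canonical_labels(l2)
    K1, K2 = int(l1.max()) + 1, int(l2.max()) + 1
    C = np.zeros((K1, K2), dtype=int)
    np.add.at(C, (l1, l2), 1)
    best = 0
    targets = list(range(K2)) + [-1] * K1  # -1 = unmatched
    for assign in itertools.permutations(targets, K1):
        if len([a for a in assign if a >= 0]) != len({a for a in assign if a >= 0}):
            continue
        best = max(best, sum(C[i, a] for i, a in enumerate(assign) if a >= 0))
    return best


def exact_posterior(a1, a2, J, alpha, lam):
    """Exact posterior over all set partitions: CRP prior times the
    integrated Dirichlet-multinomial marginal."""
    n = a1.shape[0]
    parts = list(set_partitions(n))
    lp = np.array([
        log_partition_prior(np.array(p), alpha)
        + log_marginal_partition(a1, a2, np.array(p), J, lam)
        for p in parts
    ])
    post = np.exp(lp - lp.max())
    post /= post.sum()
    return parts, post


def exhaustive_mean_partition(samples):
    """Mean partition by exhaustive search over all partitions (n <= 7),
    using the brute-force distance.  Returns (labels, D)."""
    samples = [np.asarray(s) for s in samples]
    n = samples[0].size
    best, best_d = None, np.inf
    for p in set_partitions(n):
        u = np.array(p)
        d = sum(brute_force_distance(u, s) for s in samples)
        if d < best_d:
            best, best_d = u, d
    return best, best_d
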