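"""Summaries of sampled partitions.

* partition distance — the minimum number of individuals that must be
  removed from both partitions to make them identical, computed as a
  maximum-overlap assignment problem (Hungarian algorithm) and usually
  reported normalised by n;
* a size-weighted variant for unbalanced designs, where each individual
  carries a positive weight and the removed weight is minimised;
* the mean partition — the partition minimising the summed distance to
  all posterior samples, found by greedy single-individual moves;
* the co-assignment matrix and its complete-linkage dendrogram;
* the posterior distribution of the number of clusters K.

All summaries operate on label vectors and are invariant to cluster
relabelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from . import _kernels
from .partition import canonical_labels

_DP_K_LIMIT = 10  # bitmask-DP assignment limit inside the compiled search


def _overlap_matrix(l1, l2, weights=None) -> np.ndarray:
    K1 = int(l1.max()) + 1
    K2 = int(l2.max()) + 1
    C = np.zeros((K1, K2))
    np.add.at(C, (l1, l2), 1.0 if weights is None else weights)
    return C


def _max_overlap(C: np.ndarray) -> float:
    K1, K2 = C.shape
    if K1 != K2:  # pad square; zero rows/cols are harmless
        m = max(K1, K2)
        P = np.zeros((m, m))
        P[:K1, :K2] = C
        C = P
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].sum())


def partition_distance(p1, p2, normalized: bool = False) -> float:
    """Minimum number of individuals to remove from both partitions so
    they coincide: n minus the best total cluster overlap under an
    optimal matching.  With ``normalized`` the count is divided by n."""
    l1 = canonical_labels(p1)
    l2 = canonical_labels(p2)
    if l1.size != l2.size:
        raise ValueError("partitions must cover the same individuals")
    d = l1.size - _max_overlap(_overlap_matrix(l1, l2))
    return d / l1.size if normalized else d


def weighted_partition_distance(p_true, p_inferred, weights=None) -> float:
    """Size-weighted normalised partition distance.

    Each individual carries a positive weight; the distance is the
    minimum total weight removed under an optimal cluster matching,
    divided by the total weight.  By default weights are derived from
    the true partition so every true cluster carries equal total weight
    (an individual in a cluster of size s gets weight max_size/s — e.g.
    30 per small-cluster individual for sizes 10 and 300).
    """
    lt = canonical_labels(p_true)
    li = canonical_labels(p_inferred)
    if lt.size != li.size:
        raise ValueError("partitions must cover the same individuals")
    if weights is None:
        sizes = np.bincount(lt)
        weights = (sizes.max() / sizes)[lt]
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (lt.size,) or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per individual")
    total = weights.sum()
    return float((total - _max_overlap(_overlap_matrix(lt, li, weights))) / total)


def _stack_samples(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=np.int64)
    if arr.ndim == 1:
        arr = arr[None, :]
    return np.vstack([canonical_labels(r) for r in arr])


def mean_partition(samples, weights=None, init=None):
    """Mean partition of a set of sampled partitions.

    Starts from the stored sample with the smallest total distance and
    greedily moves single individuals (to each existing cluster and to a
    new one, individuals in index order), keeping strict improvements,
    until no move decreases the total distance D = sum_i d(eta_i, u).

    Returns ``(labels, D)`` where D is the summed (unnormalised,
    optionally weighted) distance over all samples.
    """
    arr = _stack_samples(samples)
    v, n = arr.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    samp_k = uniq.max(axis=1).astype(np.int64) + 1
    use_dp = samp_k.max() <= _DP_K_LIMIT

    def total_distance(u):
        lu = canonical_labels(u)
        return sum(
            c * (w.sum() - _max_overlap(_overlap_matrix(lu, s, w)))
            for s, c in zip(uniq, counts)
        )

    if init is None:
        if use_dp:
            dists = [
                _kernels._distance_to_samples(
                    u, int(k), uniq, samp_k, counts.astype(np.float64), w,
                    np.zeros((n + 2, n + 2)), np.zeros(1 << _DP_K_LIMIT))
                for u, k in zip(uniq, samp_k)
            ]
        else:
            dists = [total_distance(u) for u in uniq]
        u0 = uniq[int(np.argmin(dists))].copy()
    else:
        u0 = canonical_labels(init)

    if use_dp:
        u, _, D = _kernels.mean_partition_greedy(
            u0, uniq, samp_k, counts.astype(np.float64), w)
        return canonical_labels(u), float(D)

    # fallback for many clusters: same greedy sweep in Python
    u = u0.copy()
    D = total_distance(u)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            base = u[i]
            K_u = int(u.max()) + 1
            best, bestj = D, -1
            for j in range(K_u + 1):
                if j == base:
                    continue
                u[i] = j
                Dp = total_distance(u)
                if Dp < best:
                    best, bestj = Dp, j
            u[i] = base
            if bestj >= 0:
                u[i] = bestj
                u = canonical_labels(u)
                D = best
                improved = True
    return canonical_labels(u), float(D)


def coassignment_matrix(samples) -> np.ndarray:
    """n x n matrix of pairwise co-assignment probabilities across the
    sampled partitions (diagonal 1, symmetric)."""
    arr = _stack_samples(samples)
    v, n = arr.shape
    C = np.zeros((n, n))
    for row in arr:
        C += row[:, None] == row[None, :]
    return C / v


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def coassignment_dendrogram(samples, labels=None):
    """Complete-linkage dendrogram on dissimilarity 1 - co-assignment.

    Returns ``(coassignment matrix, scipy linkage matrix, newick string)``.
    """
    C = coassignment_matrix(samples)
    n = C.shape[0]
    if labels is None:
        labels = [f"ind{i}" for i in range(n)]
    dis = 1.0 - C
    np.fill_diagonal(dis, 0.0)
    Z = hierarchy.linkage(squareform(dis, checks=False), method="complete")
    return C, Z, _linkage_to_newick(Z, list(labels))


def cut_dendrogram(Z: np.ndarray, height: float) -> np.ndarray:
    """Cluster labels from cutting the dendrogram at a dissimilarity."""
    return canonical_labels(hierarchy.fcluster(Z, t=height, criterion="distance"))


def posterior_k(samples) -> tuple[pd.Series, float]:
    """Histogram of K across sampled partitions and its mean."""
    arr = _stack_samples(samples)
    ks = arr.max(axis=1) + 1
    support, freq = np.unique(ks, return_counts=True)
    return pd.Series(freq / len(ks), index=support, name="probability"), float(ks.mean())
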