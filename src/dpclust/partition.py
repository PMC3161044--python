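"""Partitions of individuals into non-empty clusters.

A partition is represented as a length-n integer label vector.  The
canonical form numbers clusters by order of first appearance, so two
label vectors describe the same partition iff their canonical forms are
bit-identical.
"""

from __future__ import annotations

import numpy as np


def canonical_labels(labels) -> np.ndarray:
    """Renumber cluster labels by first appearance (0, 1, 2, ...)."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping)
        out[i] = mapping[key]
    return out


def cluster_sizes(labels) -> np.ndarray:
    """Sizes |S_j| of the clusters of a canonical label vector."""
    labels = canonical_labels(labels)
    return np.bincount(labels)


def n_clusters(labels) -> int:
    return int(np.asarray(labels).max()) + 1 if len(labels) else 0
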