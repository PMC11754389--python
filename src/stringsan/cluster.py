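"""Medoid clustering under the LIS-based distance, and clustering-agreement
measures.

The clustering objective is the K-median one restricted to exemplars drawn
from the data (medoids): choose K strings minimizing the summed distance of
every string to its nearest medoid.  Since the distance is not a metric,
approximation algorithms requiring the triangle inequality do not apply; we
use the classic Partitioning Around Medoids (PAM) local search, which only
needs symmetry and zero self-distance.

Agreement between two partitions is quantified by normalized mutual
information (mutual information divided by the larger of the two partition
entropies) and by a pair-counting adjusted Rand index

    ARI = 2 (N00 N11 - N01 N10) /
          ((N00 + N01)(N01 + N11) + (N00 + N10)(N10 + N11))

where Nab counts string pairs that are together (1) or apart (0) in each of
the two partitions.  Note this pair-counting form differs from the usual
expected-index-corrected (hypergeometric) ARI, which is also provided for
cross-tool comparison.  A cluster-compactness score sums, per string, the
best two-way directed LIS similarity to any medoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, lis_k
from .errors import BadK, LengthMismatch


@dataclass(frozen=True)
class Clustering:
    """K medoid indices (ascending) and per-string cluster labels in
    [0, K); labels point to the nearest medoid, ties resolved toward the
    lowest medoid index, and each medoid belongs to its own cluster."""

    medoids: tuple[int, ...]
    labels: np.ndarray
    cost: float


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, DistanceMatrix):
        return matrix.values
    return np.asarray(matrix)


def _assign(D: np.ndarray, medoids: tuple[int, ...]) -> tuple[np.ndarray, float]:
    sub = D[:, list(medoids)]
    labels = np.argmin(sub, axis=1)  # first minimum -> lowest medoid index
    for j, m in enumerate(medoids):
        labels[m] = j
    cost = float(sub[np.arange(D.shape[0]), labels].sum())
    return labels, cost


def clustering_cost(matrix, clust: Clustering) -> float:
    """Sum over strings of the distance to their assigned medoid."""
    D = _as_array(matrix)
    medoid_of = np.asarray(clust.medoids)[clust.labels]
    return float(D[np.arange(D.shape[0]), medoid_of].sum())


def pam(matrix, K: int, seed: int, n_restarts: int = 5) -> Clustering:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Initial medoids are drawn uniformly without replacement with a seeded
    generator.  The swap phase sweeps all (medoid, non-medoid) pairs in
    index order, accepts the first strictly cost-decreasing swap and
    restarts the sweep, until a full sweep yields no improvement; the
    result is 1-swap-optimal.  ``n_restarts`` independent initializations
    are run and the cheapest outcome returned (ties go to the earliest
    restart), so the procedure is deterministic given (matrix, K, seed).
    """
    D = _as_array(matrix)
    n = D.shape[0]
    if not 1 <= K <= n:
        raise BadK(f"K={K} must be in [1, {n}]")
    rng = np.random.default_rng(seed)

    best: Clustering | None = None
    for _ in range(max(1, n_restarts)):
        medoids = tuple(sorted(rng.choice(n, size=K, replace=False).tolist()))
        _, cost = _assign(D, medoids)
        improved = True
        while improved:
            improved = False
            non_medoids = [i for i in range(n) if i not in medoids]
            for mi in range(K):
                for cand in non_medoids:
                    trial = tuple(sorted(medoids[:mi] + (cand,) + medoids[mi + 1 :]))
                    _, trial_cost = _assign(D, trial)
                    if trial_cost < cost:
                        medoids, cost = trial, trial_cost
                        improved = True
                        break
                if improved:
                    break
        labels, cost = _assign(D, medoids)
        if best is None or cost < best.cost:
            best = Clustering(medoids=medoids, labels=labels, cost=cost)
    return best


def _contingency(a, b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise LengthMismatch("label vectors must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table, table.sum(axis=1), table.sum(axis=0)


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information I(C, C') / max(H(C), H(C')).

    Two single-cluster partitions agree perfectly (1.0); if exactly one
    partition is trivial the measure is 0.0.
    """
    table, a_sizes, b_sizes = _contingency(labels_a, labels_b)
    N = a_sizes.sum()
    h_a = -sum(s / N * math.log(s / N) for s in a_sizes if s)
    h_b = -sum(s / N * math.log(s / N) for s in b_sizes if s)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    info = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij:
                info += nij / N * math.log(N * nij / (a_sizes[i] * b_sizes[j]))
    return info / max(h_a, h_b)


def _pair_counts(labels_a, labels_b) -> tuple[int, int, int, int]:
    table, a_sizes, b_sizes = _contingency(labels_a, labels_b)
    N = int(a_sizes.sum())
    total = N * (N - 1) // 2
    n11 = int((table * (table - 1) // 2).sum())
    n10 = int((a_sizes * (a_sizes - 1) // 2).sum()) - n11
    n01 = int((b_sizes * (b_sizes - 1) // 2).sum()) - n11
    n00 = total - n11 - n10 - n01
    return n00, n01, n10, n11


def ari(labels_a, labels_b, standard: bool = False) -> float:
    """Adjusted Rand index between two partitions.

    Default is the pair-counting form in the module docstring; identical
    partitions score 1 and the value can be negative.  With
    ``standard=True`` the conventional hypergeometric-expectation-corrected
    ARI is returned instead.
    """
    n00, n01, n10, n11 = _pair_counts(labels_a, labels_b)
    if standard:
        total = n00 + n01 + n10 + n11
        sum_a = n11 + n10
        sum_b = n11 + n01
        expected = sum_a * sum_b / total if total else 0.0
        max_index = (sum_a + sum_b) / 2
        if max_index == expected:
            return 1.0
        return (n11 - expected) / (max_index - expected)
    if n01 == 0 and n10 == 0:
        return 1.0  # identical partitions (also covers degenerate cases)
    denom = (n00 + n01) * (n01 + n11) + (n00 + n10) * (n10 + n11)
    return 2.0 * (n00 * n11 - n01 * n10) / denom


def lis_quality(collection, medoids, k: int) -> int:
    """Cluster-compactness score: for each string, the largest two-way
    directed LIS similarity to any medoid, summed over the collection."""
    medoids = list(medoids)
    for s in list(collection) + medoids:
        if len(s) < k:
            raise BadK("all strings must have length at least k")
    return sum(
        max(lis_k(y, m, k) + lis_k(m, y, k) for m in medoids) for y in collection
    )


__all__ = [
    "Clustering",
    "pam",
    "clustering_cost",
    "nmi",
    "ari",
    "lis_quality",
]
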