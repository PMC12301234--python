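"""Clustering-based diversification of predicted binders.

Thresholded candidates are clustered by k-medoids (PAM-style alternation) on
pairwise normalized edit distance over the full-length amino-acid sequence,
and one representative per non-empty cluster is returned: the member with the
highest predicted probability (ties broken lexicographically). This converts
a redundant prediction list into a diverse panel for reformatting.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import edlib
import numpy as np


def normalized_edit_distance(a: str, b: str) -> float:
    if not a and not b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return d / max(len(a), len(b))


def pairwise_distances(sequences: Sequence[str]) -> np.ndarray:
    n = len(sequences)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = normalized_edit_distance(sequences[i],
                                                         sequences[j])
    return D


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> np.ndarray:
    """PAM-style alternation: assign to nearest medoid, recentre each
    cluster at its cost-minimizing member. Returns cluster labels."""
    n = len(D)
    medoids = list(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                new_medoids.append(medoids[c])
                continue
            costs = D[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[int(np.argmin(costs))]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def diversify(
    candidates: Sequence[tuple[str, float]],
    n_clusters: int,
    seed: int = 0,
) -> list[tuple[str, float, int]]:
    """Pick one representative per sequence cluster.

    ``candidates`` are (sequence, predicted probability) pairs; duplicates
    are collapsed (keeping the highest probability). ``n_clusters`` above
    the number of distinct sequences is clamped with a warning. Returns
    (sequence, probability, cluster_id) sorted by cluster id.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    uniq: dict[str, float] = {}
    for seq, prob in candidates:
        if seq not in uniq or prob > uniq[seq]:
            uniq[seq] = prob
    seqs = sorted(uniq)
    if not seqs:
        return []
    if n_clusters > len(seqs):
        warnings.warn(f"n_clusters={n_clusters} clamped to {len(seqs)} "
                      "distinct sequences")
        n_clusters = len(seqs)
    rng = np.random.default_rng(seed)
    D = pairwise_distances(seqs)
    labels = _kmedoids(D, n_clusters, rng)
    out = []
    for c in sorted(set(labels)):
        members = [seqs[i] for i in np.flatnonzero(labels == c)]
        rep = min(members, key=lambda s: (-uniq[s], s))
        out.append((rep, uniq[rep], int(c)))
    return out
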