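"""Independent brute-force oracles used by the test suite only.

The naive agglomerator recomputes every inter-cluster dissimilarity from the
ORIGINAL distance matrix (or, for Ward, from the original coordinates via
the within-cluster sum-of-squares increase) at every step - no recurrence
updates - so it shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Sequence, Set

import numpy as np


def naive_linkage_distance(
    members_a: Sequence[int],
    members_b: Sequence[int],
    D: np.ndarray,
    linkage: str,
    X: Optional[np.ndarray] = None,
) -> float:
    pairs = [D[i, j] for i in members_a for j in members_b]
    if linkage == "single":
        return min(pairs)
    if linkage == "complete":
        return max(pairs)
    if linkage == "average":
        return float(np.mean(pairs))
    if linkage == "ward":
        # ward.D2 height: sqrt(2 * increase in within-cluster SSE)
        ca = X[list(members_a)].mean(axis=0)
        cb = X[list(members_b)].mean(axis=0)
        na, nb = len(members_a), len(members_b)
        d2 = float(((ca - cb) ** 2).sum())
        return math.sqrt(2.0 * na * nb / (na + nb) * d2)
    raise ValueError(linkage)


def naive_agglomerate(
    D: np.ndarray, linkage: str, X: Optional[np.ndarray] = None
) -> tuple:
    """Returns (heights, partitions) where partitions[t] is the set of
    frozenset clusters after merge t."""
    n = D.shape[0]
    clusters: List[Set[int]] = [{i} for i in range(n)]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for (ia, a), (ib, b) in itertools.combinations(enumerate(clusters), 2):
            d = naive_linkage_distance(sorted(a), sorted(b), D, linkage, X)
            if best is None or d < best[0] - 1e-12:
                best = (d, ia, ib)
        d, ia, ib = best
        merged = clusters[ia] | clusters[ib]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
        heights.append(d)
        partitions.append({frozenset(c) for c in clusters})
    return np.array(heights), partitions


def naive_silhouette(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) - {labels[i]}
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def naive_jaccard(a, b) -> float:
    a, b = set(a), set(b)
    inter = sum(1 for x in a if x in b)
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0
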