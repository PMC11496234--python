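"""Agglomerative hierarchical clustering, written out in full.

Implements the four candidate linkages (single, complete, average, Ward)
via the Lance-Williams recurrences, the Kaufman-Rousseeuw agglomerative
coefficient, tree cutting, silhouette widths, and the two model-selection
steps used by the pipeline: linkage selection by agglomerative coefficient
and k selection by average silhouette.

Ward dialects: the default "ward.D2" runs the Lance-Williams update on
squared Euclidean distances and reports merge heights square-rooted back to
the original distance scale (the convention of agnes/scipy for Euclidean
input); "ward.D" applies the same update to the unsquared dissimilarities.

Ties at equal merge cost are broken by the lowest (slot_a, slot_b) pair of
current cluster slots, where a merged cluster keeps the lower slot of its
two parents - deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

LINKAGES = ("single", "complete", "average", "ward")
_LINKAGE_CODE = {"single": 0, "complete": 1, "average": 2, "ward": 3}
#: Priority used to break exact ties in linkage selection.
LINKAGE_PRIORITY = ("ward", "average", "complete", "single")


@dataclass
class DistanceMatrix:
    """Condensed pairwise Euclidean distances over n observations."""

    n: int
    condensed: np.ndarray

    def full(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)

    @classmethod
    def from_points(cls, X: np.ndarray) -> "DistanceMatrix":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return cls(n=X.shape[0], condensed=pdist(X, metric="euclidean"))

    @classmethod
    def from_full(cls, D: np.ndarray) -> "DistanceMatrix":
        D = np.asarray(D, dtype=float)
        return cls(n=D.shape[0], condensed=squareform(D, checks=False))


def euclidean_distance_matrix(X: np.ndarray) -> DistanceMatrix:
    """d(i, j) = sqrt(sum_c (x_ic - x_jc)^2)."""
    return DistanceMatrix.from_points(X)


@njit(cache=True)
def _agglomerate_core(d: np.ndarray, code: int) -> np.ndarray:  # pragma: no cover
    """Lance-Williams agglomeration on a full working-scale distance matrix.

    ``d`` is modified in place. Returns the (n-1, 4) merge table
    [id_a, id_b, height, size] with scipy-style ids (originals 0..n-1, new
    clusters numbered from n) and heights on the working scale.
    """
    n = d.shape[0]
    INF = np.inf
    for i in range(n):
        d[i, i] = INF
    active = np.ones(n, dtype=np.bool_)
    size = np.ones(n, dtype=np.float64)
    cid = np.arange(n).astype(np.float64)
    # per-slot nearest neighbour cache
    nn = np.empty(n, dtype=np.int64)
    mind = np.empty(n, dtype=np.float64)
    for i in range(n):
        best, bj = INF, -1
        for j in range(n):
            if j != i and d[i, j] < best:
                best, bj = d[i, j], j
        mind[i] = best
        nn[i] = bj

    Z = np.empty((n - 1, 4), dtype=np.float64)
    next_id = float(n)
    for step in range(n - 1):
        # global minimum over active slots; first occurrence -> lowest slot
        best, bi = INF, -1
        for i in range(n):
            if active[i] and mind[i] < best:
                best, bi = mind[i], i
        bj = nn[bi]
        a, b = (bi, bj) if bi < bj else (bj, bi)
        h = d[a, b]
        na, nb = size[a], size[b]
        ida, idb = cid[a], cid[b]

        # Lance-Williams update of distances from the merged cluster (slot a)
        for k in range(n):
            if not active[k] or k == a or k == b:
                continue
            dak, dbk = d[a, k], d[b, k]
            if code == 0:
                new = dak if dak < dbk else dbk
            elif code == 1:
                new = dak if dak > dbk else dbk
            elif code == 2:
                new = (na * dak + nb * dbk) / (na + nb)
            else:
                nk = size[k]
                new = ((na + nk) * dak + (nb + nk) * dbk - nk * h) / (na + nb + nk)
            d[a, k] = new
            d[k, a] = new

        active[b] = False
        size[a] = na + nb
        lo = ida if ida < idb else idb
        hi = idb if ida < idb else ida
        Z[step, 0] = lo
        Z[step, 1] = hi
        Z[step, 2] = h
        Z[step, 3] = na + nb
        cid[a] = next_id
        next_id += 1.0

        # refresh caches
        best, bj2 = INF, -1
        for k in range(n):
            if active[k] and k != a and d[a, k] < best:
                best, bj2 = d[a, k], k
        mind[a] = best
        nn[a] = bj2
        for k in range(n):
            if not active[k] or k == a:
                continue
            if nn[k] == a or nn[k] == b:
                bk, bj3 = INF, -1
                for m in range(n):
                    if active[m] and m != k and d[k, m] < bk:
                        bk, bj3 = d[k, m], m
                mind[k] = bk
                nn[k] = bj3
            elif d[a, k] < mind[k]:
                mind[k] = d[a, k]
                nn[k] = a
    return Z


@dataclass
class MergeHistory:
    """Full agglomeration record for one linkage.

    ``Z`` follows the scipy convention: row t merges ids Z[t,0] and Z[t,1]
    (originals are 0..n-1, the cluster created at row t gets id n+t) at
    height Z[t,2] into a cluster of size Z[t,3]. Heights are on the original
    (unsquared) distance scale.
    """

    Z: np.ndarray
    n: int
    linkage: str
    ward_dialect: Optional[str] = None

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def first_merge_heights(self) -> np.ndarray:
        """Height at which each original observation is first merged."""
        m = np.empty(self.n)
        for row in self.Z:
            for id_ in (int(row[0]), int(row[1])):
                if id_ < self.n:
                    m[id_] = row[2]
        return m

    def to_merge_table(self) -> np.ndarray:
        """(n-1) x 4 table with negative indices for original observations.

        Cluster formed at row t (1-based t) is referenced as +t, original
        observation i as -(i+1) - the R hclust/agnes export convention.
        """
        out = np.empty_like(self.Z)
        for t, row in enumerate(self.Z):
            for c in (0, 1):
                id_ = int(row[c])
                out[t, c] = -(id_ + 1) if id_ < self.n else id_ - self.n + 1
            out[t, 2] = row[2]
            out[t, 3] = row[3]
        return out

    def to_newick(self, labels: Optional[Sequence[str]] = None) -> str:
        """Dendrogram as a Newick string with height-difference branch lengths."""
        if labels is None:
            labels = [str(i) for i in range(self.n)]
        node: Dict[int, Tuple[str, float]] = {
            i: (str(labels[i]), 0.0) for i in range(self.n)
        }
        for t, row in enumerate(self.Z):
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            sa, ha = node.pop(a)
            sb, hb = node.pop(b)
            node[self.n + t] = (
                f"({sa}:{max(h - ha, 0.0):.10g},{sb}:{max(h - hb, 0.0):.10g})",
                h,
            )
        tree, _ = node[self.n + len(self.Z) - 1]
        return tree + ";"


def agglomerate(
    D: DistanceMatrix, linkage: str, ward_dialect: str = "ward.D2"
) -> MergeHistory:
    """Run the full agglomeration for one linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if D.n < 2:
        raise ValueError("need at least 2 observations")
    d = D.full()
    if linkage == "ward":
        if ward_dialect not in ("ward.D", "ward.D2"):
            raise ValueError(f"unknown Ward dialect {ward_dialect!r}")
        if ward_dialect == "ward.D2":
            d = d ** 2
    Z = _agglomerate_core(np.ascontiguousarray(d), _LINKAGE_CODE[linkage])
    if linkage == "ward" and ward_dialect == "ward.D2":
        Z = Z.copy()
        Z[:, 2] = np.sqrt(np.maximum(Z[:, 2], 0.0))
    return MergeHistory(
        Z=Z, n=D.n, linkage=linkage,
        ward_dialect=ward_dialect if linkage == "ward" else None,
    )


def agglomerative_coefficient(history: MergeHistory) -> float:
    """Kaufman-Rousseeuw AC: mean over observations of 1 - m(i)/h_final."""
    h_final = float(history.Z[-1, 2])
    if h_final == 0.0:
        warnings.warn("all points identical; agglomerative coefficient defined as 0")
        return 0.0
    m = history.first_merge_heights()
    return float(np.mean(1.0 - m / h_final))


def cut_tree(history: MergeHistory, k: int) -> np.ndarray:
    """Labels 1..k after undoing the last k-1 merges.

    Clusters are numbered by first occurrence in observation order.
    """
    n = history.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(history.Z[t, 0]), int(history.Z[t, 1])
        parent[find(a)] = parent[find(b)] = n + t
    labels = np.zeros(n, dtype=int)
    seen: Dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[i] = seen[root]
    return labels


def silhouette(D: DistanceMatrix, labels: np.ndarray) -> Tuple[np.ndarray, float]:
    """Per-point silhouette widths and their mean.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean within-cluster
    distance (excluding self) and b(i) the smallest mean distance to another
    cluster; members of singleton clusters get s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = D.full()
    onehot = (labels[:, None] == uniq[None, :]).astype(float)  # (n, k)
    sums = d @ onehot  # (n, k) summed distance to each cluster
    counts = onehot.sum(axis=0)  # (k,)
    own = onehot.argmax(axis=1)
    n = len(labels)
    own_count = counts[own]
    a = np.where(own_count > 1, sums[np.arange(n), own] / np.maximum(own_count - 1, 1), 0.0)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where((own_count > 1) & (denom > 0), (b - a) / denom, 0.0)
    return s, float(s.mean())


def select_linkage(
    D: DistanceMatrix, ward_dialect: str = "ward.D2"
) -> Tuple[str, Dict[str, float]]:
    """Pick the linkage with the highest agglomerative coefficient.

    Exact ties resolve by the documented priority ward > average > complete
    > single.
    """
    if D.n < 3:
        raise ValueError("linkage selection needs at least 3 observations")
    ac = {
        name: agglomerative_coefficient(agglomerate(D, name, ward_dialect))
        for name in LINKAGES
    }
    best = max(LINKAGE_PRIORITY, key=lambda name: (ac[name], -LINKAGE_PRIORITY.index(name)))
    return best, ac


def select_k(
    D: DistanceMatrix,
    history: MergeHistory,
    k_range: Sequence[int] = tuple(range(2, 9)),
) -> Tuple[int, Dict[int, float]]:
    """Pick k maximizing the average silhouette; ties go to the smallest k."""
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty k range")
    if any(k < 2 or k > D.n - 1 for k in k_range):
        raise ValueError(f"k range {k_range} outside [2, {D.n - 1}]")
    curve: Dict[int, float] = {}
    for k in sorted(k_range):
        _, mean_s = silhouette(D, cut_tree(history, k))
        curve[k] = mean_s
    best = max(sorted(curve), key=lambda k: (curve[k], -k))
    return best, curve


@dataclass
class ClusterSolution:
    """A cut dendrogram with its quality indices."""

    labels: np.ndarray  # values in 1..k
    k: int
    mean_silhouette: float
    per_point_silhouette: np.ndarray
    agglomerative_coefficient: float
    linkage: str


def cluster_solution(
    D: DistanceMatrix, history: MergeHistory, k: int
) -> ClusterSolution:
    labels = cut_tree(history, k)
    per_point, mean_s = silhouette(D, labels)
    return ClusterSolution(
        labels=labels,
        k=k,
        mean_silhouette=mean_s,
        per_point_silhouette=per_point,
        agglomerative_coefficient=agglomerative_coefficient(history),
        linkage=history.linkage,
    )
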