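"""Cluster existence and stability testing.

Two complementary checks of a hierarchical cluster solution:

* ``gaussian_null_test`` - a parametric-simulation test of cluster
  existence. A single multivariate Gaussian is fitted to the observed
  feature matrix; M synthetic datasets of the same size are drawn from it
  and pushed through the identical clustering pipeline (same linkage, same
  fixed k, same feature scaling). The observed mean silhouette is compared
  against the null distribution with the add-one Monte-Carlo p-value
  p = (1 + #{null >= observed}) / (M + 1), which is never exactly zero.

* ``bootstrap_stability`` - nonparametric resampling stability in the
  clusterboot style. Each of B bootstrap resamples is reclustered; every
  original cluster is matched to its most-similar bootstrap cluster by
  Jaccard similarity computed on the distinct original indices present in
  the resample. A cluster with mean Jaccard > 0.7 over resamples is deemed
  stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Set

import numpy as np

from .hclust import DistanceMatrix, agglomerate, cut_tree, select_k, silhouette

STABILITY_THRESHOLD = 0.7


def jaccard(a: Set, b: Set) -> float:
    """|a & b| / |a | b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _scale_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _cluster(
    X: np.ndarray,
    k: int,
    linkage: str,
    ward_dialect: str,
    scale: bool,
    reselect_k: bool = False,
    k_range: Sequence[int] = tuple(range(2, 9)),
) -> tuple:
    """The shared observed/null/bootstrap clustering path."""
    if scale:
        X = _scale_columns(X)
    D = DistanceMatrix.from_points(X)
    hist = agglomerate(D, linkage, ward_dialect)
    if reselect_k:
        k, _ = select_k(D, hist, k_range)
    labels = cut_tree(hist, k)
    _, mean_s = silhouette(D, labels)
    return labels, mean_s


@dataclass
class NullTestResult:
    observed_mean_silhouette: float
    null_silhouettes: np.ndarray
    p_value: float
    M: int
    seed: int
    k: int
    linkage: str


def gaussian_null_test(
    X: np.ndarray,
    k: int,
    linkage: str,
    M: int = 999,
    seed: int = 0,
    *,
    ward_dialect: str = "ward.D2",
    scale: bool = True,
    covariance: str = "full",
    ridge: float = 0.0,
    reselect_k: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> NullTestResult:
    """Test the observed mean silhouette against a single-Gaussian null.

    ``covariance`` chooses the fitted null: "full" (sample covariance,
    default) or "diagonal" (independent features). A singular covariance is
    an error unless a positive ``ridge`` is added to the diagonal.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3 * k:
        raise ValueError(f"n={n} too small for k={k}")
    if M < 19:
        raise ValueError("need at least 19 null simulations")
    if rng is None:
        rng = np.random.default_rng(seed)

    mean = X.mean(axis=0)
    if covariance == "full":
        cov = np.cov(X, rowvar=False)
    elif covariance == "diagonal":
        cov = np.diag(X.var(axis=0, ddof=1))
    else:
        raise ValueError(f"unknown covariance mode {covariance!r}")
    cov = cov + ridge * np.eye(p)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular covariance for the Gaussian null; consider a ridge > 0"
        )

    _, observed = _cluster(X, k, linkage, ward_dialect, scale)
    null = np.empty(M)
    for m in range(M):
        sim = mean + rng.standard_normal((n, p)) @ chol.T
        _, null[m] = _cluster(sim, k, linkage, ward_dialect, scale, reselect_k)
    p_value = (1.0 + np.sum(null >= observed)) / (M + 1.0)
    return NullTestResult(
        observed_mean_silhouette=observed,
        null_silhouettes=null,
        p_value=float(p_value),
        M=M,
        seed=seed,
        k=k,
        linkage=linkage,
    )


@dataclass
class StabilityResult:
    mean_jaccard: np.ndarray  # (k,) per original cluster
    stable: np.ndarray  # (k,) bool, mean > 0.7
    jaccard_matrix: np.ndarray  # (B, k)
    B: int
    seed: int
    k: int
    linkage: str
    n_redrawn: int = 0
    threshold: float = STABILITY_THRESHOLD


def bootstrap_stability(
    X: np.ndarray,
    k: int,
    linkage: str,
    B: int = 100,
    seed: int = 0,
    *,
    ward_dialect: str = "ward.D2",
    scale: bool = True,
    rng: Optional[np.random.Generator] = None,
    resample_hook=None,
) -> StabilityResult:
    """Bootstrap Jaccard stability of the k-cluster solution.

    ``resample_hook``, if given, replaces bootstrap index drawing (it is
    called with (rng, n) and must return an index array) - used to verify
    the identity-resample invariant in tests.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3 * k:
        raise ValueError(f"n={n} too small for k={k}")
    if B < 20:
        raise ValueError("need at least 20 bootstrap resamples")
    if rng is None:
        rng = np.random.default_rng(seed)

    original_labels, _ = _cluster(X, k, linkage, ward_dialect, scale)
    original_sets = [set(np.flatnonzero(original_labels == c)) for c in range(1, k + 1)]

    jac = np.empty((B, k))
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = (
                resample_hook(rng, n)
                if resample_hook is not None
                else rng.integers(0, n, n)
            )
            if len(np.unique(X[idx], axis=0)) >= k:
                break
            n_redrawn += 1
        boot_labels, _ = _cluster(X[idx], k, linkage, ward_dialect, scale)
        present = set(idx.tolist())
        boot_sets = [
            set(np.unique(idx[boot_labels == c]).tolist()) for c in range(1, k + 1)
        ]
        for c, orig in enumerate(original_sets):
            orig_present = orig & present
            jac[b, c] = max(jaccard(orig_present, bs) for bs in boot_sets)

    mean_jac = jac.mean(axis=0)
    return StabilityResult(
        mean_jaccard=mean_jac,
        stable=mean_jac > STABILITY_THRESHOLD,
        jaccard_matrix=jac,
        B=B,
        seed=seed,
        k=k,
        linkage=linkage,
        n_redrawn=n_redrawn,
    )


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Pair-counting adjusted Rand index between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))
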