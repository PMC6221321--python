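"""Temporal pattern discovery among DE genes.

DE genes of one drug are clustered on their fitted log2-ratio profiles at
the observed post-exposure times with Hartigan-Wong k-means (Euclidean
distance, best of many random restarts), the number of clusters chosen by
the average silhouette width (ASW), and clusters labelled with the modal
(direction, phase) of their members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusteringResult",
    "cluster_profiles",
    "select_k_by_asw",
    "label_clusters",
    "profiles_from_fits",
]

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _hartigan_wong(X, assign, centers, sizes, max_sweeps):
    """Hartigan-Wong refinement: move a point to the cluster giving the
    largest decrease in total within-cluster sum of squares, using the
    size-corrected transfer gains; sweeps until no move improves."""
    n, p = X.shape
    K = centers.shape[0]
    for _ in range(max_sweeps):
        moved = 0
        for i in range(n):
            a = assign[i]
            na = sizes[a]
            if na <= 1:
                continue
            # removal cost from current cluster
            da = 0.0
            for j in range(p):
                d = X[i, j] - centers[a, j]
                da += d * d
            removal = na / (na - 1.0) * da
            best_gain = removal
            best_b = a
            for b in range(K):
                if b == a:
                    continue
                nb = sizes[b]
                db = 0.0
                for j in range(p):
                    d = X[i, j] - centers[b, j]
                    db += d * d
                gain = nb / (nb + 1.0) * db
                if gain < best_gain - 1e-12:
                    best_gain = gain
                    best_b = b
            if best_b != a:
                nb = sizes[best_b]
                for j in range(p):
                    centers[a, j] = (centers[a, j] * na - X[i, j]) / (na - 1.0)
                    centers[best_b, j] = (centers[best_b, j] * nb + X[i, j]) / (nb + 1.0)
                sizes[a] = na - 1
                sizes[best_b] = nb + 1
                assign[i] = best_b
                moved += 1
        if moved == 0:
            break
    # total within-cluster SS
    ss = 0.0
    for i in range(n):
        a = assign[i]
        for j in range(p):
            d = X[i, j] - centers[a, j]
            ss += d * d
    return ss


def _init_assign(X: np.ndarray, center_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = X[center_idx].copy()
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    # keep seeds in their own cluster so none starts empty
    assign[center_idx] = np.arange(len(center_idx))
    K = centers.shape[0]
    sizes = np.bincount(assign, minlength=K)
    for k in range(K):
        centers[k] = X[assign == k].mean(axis=0)
    return assign.astype(np.int64), centers.astype(np.float64), sizes.astype(np.int64)


@dataclass
class ClusteringResult:
    K: int
    assignments: pd.Series          # gene -> cluster id (0..K-1)
    centroids: np.ndarray           # K x profile length
    within_ss: float
    asw: float
    asw_by_k: dict[int, float] = field(default_factory=dict)
    labels: dict[int, tuple[str, str]] = field(default_factory=dict)


def cluster_profiles(
    profiles: pd.DataFrame,
    K: int,
    n_restarts: int = 1000,
    seed: int = 0,
    max_sweeps: int = 100,
) -> ClusteringResult:
    """Best-of-restarts Hartigan-Wong k-means of gene profiles.

    ``profiles``: DataFrame, genes (index) x profile coordinates.  Restarts
    draw K distinct genes as initial centers; the solution with the smallest
    within-cluster sum of squares wins.  Deterministic given ``seed``.
    """
    X = profiles.to_numpy(float)
    n = X.shape[0]
    if K < 2 or K > n:
        raise ValueError(f"K must be in [2, n_profiles={n}], got {K}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best_ss = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        center_idx = rng.choice(n, size=K, replace=False)
        assign, centers, sizes = _init_assign(X, center_idx)
        ss = _hartigan_wong(X, assign, centers, sizes, max_sweeps)
        if ss < best_ss - 1e-12:
            best_ss = ss
            best = (assign.copy(), centers.copy())
    assert best is not None
    assign, centers = best
    if K >= 2 and np.unique(assign).size >= 2 and n > K:
        asw = float(silhouette_score(X, assign, metric="euclidean"))
    else:
        asw = 0.0
    return ClusteringResult(
        K=K,
        assignments=pd.Series(assign, index=profiles.index, name="cluster"),
        centroids=centers,
        within_ss=float(max(best_ss, 0.0)),
        asw=asw,
    )


def select_k_by_asw(
    profiles: pd.DataFrame,
    k_range: range | list[int] = range(2, 11),
    n_restarts: int = 1000,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster at every K in ``k_range`` and keep the ASW-maximizing result
    (ties to the smaller K)."""
    ks = [k for k in k_range if 2 <= k <= len(profiles) - 1]
    if not ks:
        raise ValueError("k_range empty after restriction to [2, n_profiles-1]")
    results: dict[int, ClusteringResult] = {}
    for k in sorted(ks):
        results[k] = cluster_profiles(profiles, k, n_restarts=n_restarts, seed=seed + k)
    best_k = max(sorted(results), key=lambda k: results[k].asw)
    for k in sorted(results):  # ties -> smaller K
        if results[k].asw >= results[best_k].asw - 1e-12:
            best_k = k
            break
    chosen = results[best_k]
    chosen.asw_by_k = {k: results[k].asw for k in sorted(results)}
    return chosen


_PHASE_ORDER = {"IE": 0, "M": 1, "L": 2}


def label_clusters(result: ClusteringResult, deg_calls: pd.DataFrame) -> dict[int, tuple[str, str]]:
    """Label each cluster with the modal (direction, phase) of its members;
    ties break to the earlier phase, then to "up".

    ``deg_calls`` is the DE table (index = gene) with ``direction`` and
    ``phase`` columns.
    """
    labels: dict[int, tuple[str, str]] = {}
    for k in range(result.K):
        members = result.assignments.index[result.assignments == k]
        counts: dict[tuple[str, str], int] = {}
        for g in members:
            if g not in deg_calls.index:
                raise KeyError(f"gene {g} has no DE call")
            row = deg_calls.loc[g]
            key = (str(row["direction"]), str(row["phase"]))
            counts[key] = counts.get(key, 0) + 1
        if not counts:
            continue
        labels[k] = min(
            counts,
            key=lambda dp: (-counts[dp], _PHASE_ORDER.get(dp[1], 9), 0 if dp[0] == "up" else 1),
        )
    result.labels = labels
    return labels


def profiles_from_fits(fits, genes: list[str], times: np.ndarray | None = None) -> pd.DataFrame:
    """Fitted log2 ratios (fitted(t) - fitted(0)) at the observed
    post-exposure times, the clustering feature space."""
    if times is None:
        times = np.array([1.0, 2.0, 4.0, 8.0])
    cols = []
    for t in times:
        j = int(np.argmin(np.abs(fits.grid - t)))
        cols.append(fits.log2_ratio[:, j])
    mat = np.column_stack(cols)
    frame = pd.DataFrame(mat, index=fits.gene_ids, columns=[f"t{t:g}" for t in times])
    return frame.loc[genes]
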