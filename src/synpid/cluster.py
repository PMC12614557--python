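"""k-medoids clustering (classical PAM) on information dissimilarities.

PAM = BUILD (greedy medoid seeding) + SWAP (best single medoid/non-medoid
exchange until no exchange lowers the cost).  The number of clusters is
chosen by maximizing the mean silhouette width over k = 2..10, the
standard heuristic for medoid clustering on a precomputed dissimilarity.

Two dissimilarity conventions are supported: the target-averaged synergy
matrix is already a dissimilarity (``direct``: negatives clipped to 0),
while a pairwise-MI matrix is a similarity and is inverted as
``max(M) - M`` (``max_minus``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "DissimilarityMatrix",
    "ClusteringResult",
    "to_dissimilarity",
    "pam",
    "silhouette_mean",
    "select_k",
    "PAMedoids",
]


@dataclass
class DissimilarityMatrix:
    d: np.ndarray
    node_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        _validate_dissimilarity(self.d)
        if not self.node_ids:
            self.node_ids = [f"node{i}" for i in range(self.d.shape[0])]


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray
    labels: np.ndarray
    cost: float
    silhouette: float


def _validate_dissimilarity(d: np.ndarray):
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("dissimilarity must be finite")
    if np.any(d < 0):
        raise ValueError("dissimilarity must be non-negative")


def to_dissimilarity(m, mode: str = "direct") -> np.ndarray:
    """Convert a symmetric pairwise matrix into a valid dissimilarity.

    mode="direct"    : clip negatives to 0, zero the diagonal (synergy).
    mode="max_minus" : d[i,j] = max(m) - m[i,j] off-diagonal (similarity
                       such as MI), diagonal 0.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    m = (m + m.T) / 2.0
    if mode == "direct":
        d = np.clip(m, 0.0, None)
    elif mode == "max_minus":
        off = ~np.eye(m.shape[0], dtype=bool)
        d = np.zeros_like(m)
        if off.any():
            d[off] = m[off].max() - m[off]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(d, 0.0)
    return d


def _cost(d: np.ndarray, medoids) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _labels_from_medoids(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # medoids sorted ascending; ties go to the lowest-index medoid
    return np.argmin(d[:, medoids], axis=1)


def pam(d, k: int, max_swaps: int | None = None) -> ClusteringResult:
    """Classical PAM: greedy BUILD then best-improvement SWAP.

    Deterministic: all ties are broken by the lowest node index, and the
    cost is strictly non-increasing across SWAP iterations.
    """
    if isinstance(d, DissimilarityMatrix):
        d = d.d
    d = np.asarray(d, dtype=float)
    _validate_dissimilarity(d)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    if max_swaps is None:
        max_swaps = 10 * n

    # BUILD: start from the 1-medoid optimum, then greedily add the
    # point whose addition lowers the total cost the most.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        cand_cost = np.minimum(nearest[None, :], d).sum(axis=1)
        cand_cost[medoids] = np.inf
        c = int(np.argmin(cand_cost))
        medoids.append(c)
        nearest = np.minimum(nearest, d[c])

    medoids = sorted(medoids)
    cost = _cost(d, medoids)

    # SWAP: apply the single exchange with the largest cost decrease.
    for _ in range(max_swaps):
        best_cost = cost
        best_swap = None
        med_set = set(medoids)
        for mi_pos, m in enumerate(medoids):
            others = medoids[:mi_pos] + medoids[mi_pos + 1:]
            nearest_others = d[:, others].min(axis=1)
            swap_costs = np.minimum(nearest_others[None, :], d).sum(axis=1)
            for h in range(n):
                if h in med_set:
                    continue
                c = swap_costs[h]
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (m, h)
        if best_swap is None:
            break
        m, h = best_swap
        medoids = sorted(set(medoids) - {m} | {h})
        cost = best_cost

    medoids = np.asarray(medoids, dtype=int)
    labels = _labels_from_medoids(d, medoids)
    cost = _cost(d, medoids)
    sil = silhouette_mean(d, labels) if k >= 2 else 0.0
    return ClusteringResult(k=k, medoids=medoids, labels=labels, cost=cost, silhouette=sil)


def silhouette_mean(d, labels) -> float:
    """Mean silhouette width for a labeling of a precomputed dissimilarity.

    Per node: a = mean within-cluster dissimilarity (excluding self),
    b = smallest mean dissimilarity to another cluster,
    s = (b - a) / max(a, b); members of singleton clusters score 0.
    """
    if isinstance(d, DissimilarityMatrix):
        d = d.d
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = d.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own)
        if same.sum() == 1:
            widths[i] = 0.0
            continue
        a = d[i, same].sum() / (same.sum() - 1)
        b = min(d[i, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def select_k(d, kmin: int = 2, kmax: int = 10, max_swaps: int | None = None) -> ClusteringResult:
    """Run PAM for each k in [kmin, min(kmax, n-1)]; return the best silhouette.

    Ties favor the smaller k; deterministic given the matrix.
    """
    if isinstance(d, DissimilarityMatrix):
        d = d.d
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n <= kmin:
        raise ValueError(f"need more than kmin={kmin} nodes (got n={n})")
    best = None
    for k in range(kmin, min(kmax, n - 1) + 1):
        res = pam(d, k, max_swaps=max_swaps)
        if best is None or res.silhouette > best.silhouette + 1e-12:
            best = res
    return best


class PAMedoids(ClusterMixin, BaseEstimator):
    """Scikit-learn style PAM clusterer on a precomputed dissimilarity.

    Parameters
    ----------
    n_clusters : int or None
        Fixed number of medoids, or None to select k in [k_min, k_max]
        by maximizing the mean silhouette width.
    k_min, k_max : int
        Search range used when ``n_clusters`` is None.
    max_swaps : int or None
        Cap on SWAP iterations (default 10 * n).

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
    medoid_indices_ : ndarray of shape (k,)
    inertia_ : float
        Total dissimilarity of every node to its nearest medoid.
    silhouette_ : float
    n_clusters_ : int
    selection_trace_ : list of (k, cost, silhouette)
        One row per candidate k when auto-selecting (single row otherwise).
    """

    def __init__(self, n_clusters=None, k_min: int = 2, k_max: int = 10,
                 max_swaps=None):
        self.n_clusters = n_clusters
        self.k_min = k_min
        self.k_max = k_max
        self.max_swaps = max_swaps

    def fit(self, X, y=None):
        X = check_array(X)
        _validate_dissimilarity(X)
        trace = []
        if self.n_clusters is None:
            n = X.shape[0]
            best = None
            for k in range(self.k_min, min(self.k_max, n - 1) + 1):
                res = pam(X, k, max_swaps=self.max_swaps)
                trace.append((k, res.cost, res.silhouette))
                if best is None or res.silhouette > best.silhouette + 1e-12:
                    best = res
        else:
            best = pam(X, int(self.n_clusters), max_swaps=self.max_swaps)
            trace.append((best.k, best.cost, best.silhouette))
        self.labels_ = best.labels
        self.medoid_indices_ = best.medoids
        self.inertia_ = best.cost
        self.silhouette_ = best.silhouette
        self.n_clusters_ = best.k
        self.selection_trace_ = trace
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Assign new points to the nearest fitted medoid.

        ``X`` is a dissimilarity block of shape (n_new, n_train) against
        the training nodes, as with other precomputed-metric estimators.
        """
        check_is_fitted(self, "medoid_indices_")
        X = check_array(X)
        return np.argmin(X[:, self.medoid_indices_], axis=1)
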