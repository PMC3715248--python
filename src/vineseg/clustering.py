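"""Deterministic, seedable K-means used by every pipeline stage.

The clustering objective is the classical sum of squared errors

    J_K = sum_k sum_{i in C_k} ||x_i - m_k||^2

where ``m_k`` is the centroid (mean) of cluster ``C_k`` and ``n_k`` its size.
Lloyd iterations are run from a k-means++-style seeded initialisation; among
``n_restarts`` runs the model with the lowest ``J_K`` is returned.

Determinism contracts (all covered by tests):

* identical ``(X, K, seed, n_restarts)`` give a bit-for-bit identical model;
* assignment ties go to the lower cluster index;
* an empty cluster is re-seeded to the point farthest from its current
  centroid;
* returned cluster indices are canonicalised by sorting centroids
  lexicographically, so the labelling does not depend on the order in which
  the initialisation happened to visit the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

__all__ = ["ClusterModel", "kmeans_fit", "inertia", "brute_force_min_inertia"]


@dataclass
class ClusterModel:
    """Result of a K-means fit.

    Attributes
    ----------
    centroids : (K, d) array
        Cluster centres ``m_k``, sorted lexicographically by coordinates.
    assignments : (n,) int array
        Cluster index of each input point.
    inertia : float
        The objective ``J_K`` recomputed from the final assignment.
    n_per_cluster : (K,) int array
        Cluster sizes ``n_k``; sums to ``n``.
    inertia_history : list of float
        ``J_K`` after each assignment step of the winning restart
        (non-increasing by construction of Lloyd's algorithm).
    """

    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_per_cluster: np.ndarray
    inertia_history: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    def to_json(self) -> dict:
        return {
            "K": int(self.K),
            "centroids": self.centroids.tolist(),
            "inertia": float(self.inertia),
            "n_per_cluster": self.n_per_cluster.tolist(),
        }


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"X must be 1- or 2-dimensional, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise DegenerateInputError("non-finite values in clustering input")
    return X


def inertia(X, centroids, assignments) -> float:
    """Sum of squared distances of each point to its assigned centroid.

    Pure function; raises ``IndexError`` on out-of-range assignments.
    """
    X = _as_matrix(X)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    assignments = np.asarray(assignments)
    if assignments.shape[0] != X.shape[0]:
        raise ValueError("assignments length must match number of points")
    if assignments.size and (assignments.min() < 0 or assignments.max() >= len(centroids)):
        raise IndexError("assignment index out of range")
    diff = X - centroids[assignments]
    return float(np.einsum("ij,ij->", diff, diff))


def _plusplus_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then D^2-weighted."""
    n = X.shape[0]
    centres = np.empty((K, X.shape[1]))
    idx = rng.integers(n)
    centres[0] = X[idx]
    d2 = np.sum((X - centres[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0.0:
            # all remaining points coincide with a chosen centre
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centres[k] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centres[k]) ** 2, axis=1))
    return centres


def _assign(X: np.ndarray, centres: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared distances to every centre; argmin breaks ties toward lower index
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ centres.T
        + np.sum(centres * centres, axis=1)[None, :]
    )
    # exact recompute for the winning column keeps inertia non-negative
    labels = np.argmin(d2, axis=1)
    diff = X - centres[labels]
    return labels, np.sum(diff * diff, axis=1)


def _partition_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random-partition seeding: centroids are means of a random K-colouring.

    Unlike point sampling this places initial centres off-data (inside the
    convex hull), reaching optimisation basins that k-means++ provably
    cannot on some small instances.
    """
    labels = rng.integers(K, size=X.shape[0])
    centres = np.empty((K, X.shape[1]))
    for k in range(K):
        members = labels == k
        centres[k] = X[members].mean(axis=0) if members.any() else X[rng.integers(X.shape[0])]
    return centres


def _lloyd(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: str = "++",
) -> tuple[np.ndarray, np.ndarray, list]:
    if init == "partition":
        centres = _partition_init(X, K, rng)
    else:
        centres = _plusplus_init(X, K, rng)
    history: list = []
    labels = np.zeros(X.shape[0], dtype=np.intp)
    for _ in range(max_iter):
        labels, point_cost = _assign(X, centres)
        history.append(float(point_cost.sum()))
        new_centres = centres.copy()
        for k in range(K):
            members = labels == k
            if members.any():
                new_centres[k] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster to the point farthest from its
                # centroid; moving an empty cluster's centre cannot increase
                # the current assignment cost, so J_K stays monotone
                far = int(np.argmax(point_cost))
                new_centres[k] = X[far]
                point_cost[far] = 0.0
        shift = np.max(np.sqrt(np.sum((new_centres - centres) ** 2, axis=1)))
        centres = new_centres
        if shift < tol:
            break
    labels, point_cost = _assign(X, centres)
    history.append(float(point_cost.sum()))
    return centres, labels, history


def _canonicalise(
    centres: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sort clusters lexicographically by centroid coordinates and relabel."""
    order = np.lexsort(centres.T[::-1])
    remap = np.empty(len(order), dtype=np.intp)
    remap[order] = np.arange(len(order))
    return centres[order], remap[labels]


def kmeans_fit(
    X,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Fit K-means by seeded Lloyd iterations with restarts.

    Parameters
    ----------
    X : (n, d) or (n,) array
        Finite data matrix; 1-D input is treated as n points in 1 dimension.
    K : int
        Number of clusters; requires ``n >= K >= 1``.
    seed : int
        Seed for initialisation; the only source of randomness.
    n_restarts : int
        Independent initialisations; the lowest-``J_K`` model wins
        (ties go to the earlier restart).
    max_iter, tol :
        Lloyd stops when the largest centroid shift drops below ``tol``
        or after ``max_iter`` iterations.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if n < K:
        raise DegenerateInputError(f"need at least K={K} points, got n={n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list] | None = None
    for restart in range(n_restarts):
        init = "++" if restart % 2 == 0 else "partition"
        centres, labels, history = _lloyd(X, K, rng, max_iter, tol, init=init)
        j = history[-1]
        if best is None or j < best[0]:
            best = (j, centres, labels, history)
    assert best is not None
    _, centres, labels, history = best
    # final centroids = exact means of their members
    for k in range(K):
        members = labels == k
        if members.any():
            centres[k] = X[members].mean(axis=0)
    centres, labels = _canonicalise(centres, labels)
    counts = np.bincount(labels, minlength=K)
    return ClusterModel(
        centroids=centres,
        assignments=labels,
        inertia=inertia(X, centres, labels),
        n_per_cluster=counts,
        inertia_history=history,
    )


def brute_force_min_inertia(X, K: int) -> float:
    """Globally minimal ``J_K`` by exhaustive enumeration of assignments.

    Reference enumerator for validating :func:`kmeans_fit` on tiny
    instances (n <= ~12, K <= 3); cost is O(K^n). Clusters are allowed to
    be empty in the enumeration, so the result is the minimum over all
    partitions into at most K groups — which is also where the K-means
    optimum lies.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if n == 0:
        return 0.0
    if K**n > 4_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    # all K^n assignments as a (B, n) mixed-radix table, with the first point
    # pinned to cluster 0 (label symmetry) when K > 1
    B = K ** max(n - 1, 0)
    codes = np.arange(B)
    A = np.zeros((B, n), dtype=np.int8)
    for j in range(1, n):
        A[:, j] = (codes // (K ** (j - 1))) % K
    sq = np.sum(X * X, axis=1)
    total = np.zeros(B)
    for k in range(K):
        M = A == k  # (B, n)
        cnt = M.sum(axis=1)
        sx = M @ X  # (B, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            centre_term = np.where(cnt > 0, np.sum(sx * sx, axis=1) / cnt, 0.0)
        total += M @ sq - centre_term
    return float(total.min())
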