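"""Partitioning (k-center) cluster analysis.

Three families, all started from k distinct cases sampled uniformly under
the run seed and wrapped in a best-of-``n_starts`` driver:

* k-means with three classic algorithms — Lloyd–Forgy batch iteration,
  MacQueen online updating, and Hartigan's first-variation transfer method
  (the core move of the Hartigan–Wong algorithm: a point migrates when the
  exact change in total WSS, ``n_t/(n_t+1)·d(x,μ_t) − n_s/(n_s−1)·d(x,μ_s)``,
  is negative).  Objective: total within-cluster sum of squares.
* k-medoids by PAM (BUILD greedy seeding, then SWAP steepest-descent over
  all medoid/non-medoid exchanges).  Objective: sum of distances of each
  case to its medoid; medoids are actual cases.
* k-medians: alternating nearest-center assignment (Euclidean) and
  within-cluster geometric medians by Weiszfeld iteration with the standard
  subgradient (Vardi–Zhang) correction when an iterate lands on a data
  point.  Objective: sum of Euclidean distances to the cluster centers.

Labels are canonicalized by first case appearance, so a fixed seed gives a
bit-stable partition across runs and case-order permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .core import ClusterSolution, DataMatrix, DistanceSpec, Partition, pairwise_distances

__all__ = ["KCenterConfig", "kmeans", "kmedoids", "kmedians", "geometric_median"]

_ALGORITHMS = ("hartigan_wong", "macqueen", "lloyd_forgy", "pam", "kmedians")


@dataclass
class KCenterConfig:
    """Run parameters for any k-center method."""

    k: int
    algorithm: str = "hartigan_wong"
    n_starts: int = 10
    max_iter: int = 100
    tol: float = 1e-8
    seed: int | None = None
    plusplus: bool = False  # k-means++ seeding, off by default

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def _check(data: DataMatrix, cfg: KCenterConfig) -> np.ndarray:
    if cfg.k >= data.n:
        raise ValueError("k must be smaller than the number of cases")
    if not data.standardized:
        warnings.warn(
            "k-center methods are usually run on standardized variables",
            stacklevel=3,
        )
    if data.has_missing():
        raise ValueError("missing values present; run preprocessing first")
    return data.values


def _init_centers(X: np.ndarray, k: int, rng: np.random.Generator, plusplus: bool):
    n = X.shape[0]
    if not plusplus:
        idx = rng.choice(n, size=k, replace=False)
        return X[idx].copy()
    # k-means++ seeding (optional)
    centers = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(cdist(X, np.array(centers), "sqeuclidean"), axis=1)
        probs = d2 / d2.sum()
        centers.append(X[rng.choice(n, p=probs)])
    return np.array(centers)


def _wss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    tot = 0.0
    for c in range(k):
        sub = X[labels == c]
        if len(sub):
            tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return np.argmin(cdist(X, centers, "sqeuclidean"), axis=1)


def _fix_empty(X, centers, labels, k):
    """Re-seed each empty cluster at the case farthest from its center."""
    for c in range(k):
        if not np.any(labels == c):
            d = np.min(cdist(X, centers, "sqeuclidean"), axis=1)
            far = int(np.argmax(d))
            centers[c] = X[far]
            labels = _assign(X, centers)
    return centers, labels


def _lloyd(X, centers, max_iter, tol):
    k = centers.shape[0]
    prev = np.inf
    labels = _assign(X, centers)
    centers, labels = _fix_empty(X, centers, labels, k)
    for _ in range(max_iter):
        centers = np.array(
            [
                X[labels == c].mean(axis=0) if np.any(labels == c) else centers[c]
                for c in range(k)
            ]
        )
        labels = _assign(X, centers)
        centers, labels = _fix_empty(X, centers, labels, k)
        obj = _wss(X, labels, k)
        if prev - obj < tol:
            break
        prev = obj
    return labels, _wss(X, labels, k)


def _macqueen(X, centers, max_iter, tol):
    n, _ = X.shape
    k = centers.shape[0]
    centers = centers.copy()
    counts = np.zeros(k)
    labels = np.full(n, -1)
    for it in range(max_iter):
        moved = 0
        for i in range(n):
            c = int(np.argmin(((centers - X[i]) ** 2).sum(axis=1)))
            if c != labels[i]:
                moved += 1
            if labels[i] >= 0:
                old = labels[i]
                counts[old] -= 1
                if counts[old] > 0:
                    centers[old] -= (X[i] - centers[old]) / counts[old]
            labels[i] = c
            counts[c] += 1
            centers[c] += (X[i] - centers[c]) / counts[c]
        if moved == 0:
            break
    # final means of the converged assignment
    labels = _assign(X, centers)
    centers, labels = _fix_empty(X, centers, labels, k)
    return labels, _wss(X, labels, k)


def _hartigan(X, centers, max_iter, tol):
    n, _ = X.shape
    k = centers.shape[0]
    labels = _assign(X, centers)
    centers, labels = _fix_empty(X, centers, labels, k)
    means = np.array([X[labels == c].mean(axis=0) for c in range(k)])
    counts = np.bincount(labels, minlength=k).astype(float)
    for it in range(max_iter):
        moved = 0
        for i in range(n):
            s = labels[i]
            if counts[s] <= 1:
                continue
            d = ((means - X[i]) ** 2).sum(axis=1)
            gain_leave = counts[s] / (counts[s] - 1) * d[s]
            cost_join = counts / (counts + 1) * d
            cost_join[s] = np.inf
            t = int(np.argmin(cost_join))
            if cost_join[t] < gain_leave - 1e-12:
                # exact WSS-decreasing transfer; update means incrementally
                means[s] = (means[s] * counts[s] - X[i]) / (counts[s] - 1)
                means[t] = (means[t] * counts[t] + X[i]) / (counts[t] + 1)
                counts[s] -= 1
                counts[t] += 1
                labels[i] = t
                moved += 1
        if moved == 0:
            break
    return labels, _wss(X, labels, k)


def _canonical_solution(data, labels0, objective, centers_fn, meta) -> ClusterSolution:
    part = Partition(np.asarray(labels0) + 1).relabel_by_first_appearance()
    centroids = centers_fn(part)
    return ClusterSolution(
        partition=part, centroids=centroids, objective=float(objective), method_meta=meta
    )


def _mean_centroids(X, part: Partition) -> np.ndarray:
    return np.array([X[part.labels == c].mean(axis=0) for c in range(1, part.k + 1)])


def kmeans(data: DataMatrix, cfg: KCenterConfig) -> ClusterSolution:
    """k-means by the configured algorithm, best of ``cfg.n_starts`` starts."""
    X = _check(data, cfg)
    algos = {
        "lloyd_forgy": _lloyd,
        "macqueen": _macqueen,
        "hartigan_wong": _hartigan,
    }
    if cfg.algorithm not in algos:
        raise ValueError(f"{cfg.algorithm!r} is not a k-means algorithm")
    run = algos[cfg.algorithm]
    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(cfg.n_starts):
        centers = _init_centers(X, cfg.k, rng, cfg.plusplus)
        labels, obj = run(X, centers, cfg.max_iter, cfg.tol)
        if best is None or obj < best[1] - 1e-12:
            best = (labels, obj)
    labels, obj = best
    meta = {
        "method": f"kmeans/{cfg.algorithm}",
        "k": cfg.k,
        "seed": cfg.seed,
        "n_starts": cfg.n_starts,
        "distance": "squared_euclidean",
    }
    return _canonical_solution(data, labels, obj, lambda p: _mean_centroids(X, p), meta)


# ---------------------------------------------------------------- k-medoids


def _pam_build(D: np.ndarray, k: int) -> list:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    for _ in range(k - 1):
        dn = np.min(D[:, medoids], axis=1)
        # total gain of adding candidate j: sum over i of max(dn_i - d_ij, 0)
        gains = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list, max_iter: int) -> list:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        med = np.array(medoids)
        dmat = D[:, med]  # n x k
        order = np.argsort(dmat, axis=1)
        nearest = order[:, 0]
        d1 = dmat[np.arange(n), nearest]
        d2 = dmat[np.arange(n), order[:, 1]]
        best_delta, best_swap = -1e-12, None
        non_med = [h for h in range(n) if h not in medoids]
        for mi, m in enumerate(medoids):
            affected = nearest == mi
            for h in non_med:
                dh = D[:, h]
                delta = np.where(
                    affected,
                    np.minimum(dh, d2) - d1,
                    np.minimum(0.0, dh - d1),
                ).sum()
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
    return medoids


def kmedoids(data, cfg: KCenterConfig) -> ClusterSolution:
    """PAM k-medoids (BUILD + SWAP) on a DataMatrix or distance matrix.

    The default distance on raw data is squared Euclidean, matching the
    other modules; pass a precomputed matrix for anything else.  BUILD is
    deterministic, so one start suffices unless random restarts are wanted.
    """
    if isinstance(data, DataMatrix):
        _check(data, cfg)
        D = pairwise_distances(data, DistanceSpec("squared_euclidean"))
        X = data.values
    else:
        D = np.asarray(data, dtype=float)
        X = None
        if cfg.k >= D.shape[0]:
            raise ValueError("k must be smaller than the number of cases")
    medoids = _pam_build(D, cfg.k)
    medoids = _pam_swap(D, medoids, cfg.max_iter)
    labels = np.argmin(D[:, medoids], axis=1)
    obj = float(D[np.arange(D.shape[0]), np.array(medoids)[labels]].sum())
    part = Partition(labels + 1).relabel_by_first_appearance()
    # medoid of canonical cluster c
    med_by_label = {}
    for mi, m in enumerate(medoids):
        med_by_label[part.labels[m]] = m
    med_idx = np.array([med_by_label[c] for c in range(1, part.k + 1)])
    centroids = (
        X[med_idx] if X is not None else np.full((part.k, 1), np.nan)
    )
    meta = {"method": "kmedoids/pam", "k": cfg.k, "distance": "squared_euclidean"}
    return ClusterSolution(
        partition=part,
        centroids=centroids,
        objective=obj,
        method_meta=meta,
        medoid_indices=med_idx,
    )


# ---------------------------------------------------------------- k-medians


def geometric_median(X: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration.

    Uses the Vardi–Zhang correction when an iterate coincides with a data
    point, so the algorithm cannot stall on a non-optimal vertex.  In one
    dimension this reduces to the coordinate median.
    """
    X = np.asarray(X, float)
    if len(X) == 1:
        return X[0].copy()
    y = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        on_point = d < 1e-12
        if on_point.any():
            # Vardi–Zhang: treat the coincident point separately
            w = 1.0 / d[~on_point]
            T = (X[~on_point] * w[:, None]).sum(axis=0) / w.sum()
            R = ((X[~on_point] - y) / d[~on_point, None]).sum(axis=0)
            r = np.linalg.norm(R)
            eta = on_point.sum()
            if r <= eta:
                return y
            step = min(1.0, eta / r)
            y_new = (1 - step) * T + step * y
        else:
            w = 1.0 / d
            y_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def kmedians(data: DataMatrix, cfg: KCenterConfig) -> ClusterSolution:
    """k-medians: nearest-center assignment + within-cluster geometric medians."""
    X = _check(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(cfg.n_starts):
        centers = _init_centers(X, cfg.k, rng, cfg.plusplus)
        labels = np.argmin(cdist(X, centers, "euclidean"), axis=1)
        prev = np.inf
        for _ in range(cfg.max_iter):
            for c in range(cfg.k):
                if np.any(labels == c):
                    centers[c] = geometric_median(X[labels == c])
                else:
                    d = np.min(cdist(X, centers, "euclidean"), axis=1)
                    centers[c] = X[int(np.argmax(d))]
            labels = np.argmin(cdist(X, centers, "euclidean"), axis=1)
            obj = float(cdist(X, centers, "euclidean")[np.arange(len(X)), labels].sum())
            if prev - obj < cfg.tol:
                break
            prev = obj
        obj = float(cdist(X, centers, "euclidean")[np.arange(len(X)), labels].sum())
        if best is None or obj < best[1] - 1e-12:
            best = (labels.copy(), obj, centers.copy())
    labels, obj, centers = best
    part = Partition(labels + 1).relabel_by_first_appearance()
    # reorder centers to canonical labels
    reorder = np.empty(part.k, dtype=int)
    for old_c in range(cfg.k):
        mask = labels == old_c
        if mask.any():
            reorder[part.labels[np.argmax(mask)] - 1] = old_c
    centroids = centers[reorder]
    meta = {
        "method": "kmedians/weiszfeld",
        "k": cfg.k,
        "seed": cfg.seed,
        "n_starts": cfg.n_starts,
        "distance": "euclidean",
    }
    return ClusterSolution(
        partition=part, centroids=centroids, objective=obj, method_meta=meta
    )
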