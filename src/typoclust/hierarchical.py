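"""Agglomerative and divisive hierarchical clustering.

Agglomeration runs a single generic Lance–Williams engine covering eight
linkage methods (average, single, complete, centroid, median, Ward,
flexible beta, McQuitty).  Ward follows the ``ward.D`` convention: the
Lance–Williams recurrence is applied directly to the supplied distances,
which the caller is expected to make squared Euclidean (the classical
choice, under which merge heights are error-sum-of-squares increments times
two).  Centroid and median linkage likewise assume squared Euclidean input;
a warning is recorded otherwise.

Division uses the DIANA algorithm of Kaufman & Rousseeuw: at each step the
cluster with the largest diameter is split by the splinter procedure (the
seed is the object with maximal average dissimilarity to its cluster;
objects defect while they are on average closer to the splinter group than
to the remainder).  The split sequence is re-expressed as an agglomerative
merge table so tree cutting and export are uniform across both directions.

Tie-breaking everywhere is lexicographic on cluster slot indices (the slot
of a merged cluster is the smaller slot of its children), which makes every
tree deterministic and invariant, up to relabelling, under case permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataMatrix, DistanceSpec, Partition, pairwise_distances

__all__ = ["Dendrogram", "ahca", "diana", "cut_tree", "wss_series", "total_ss"]

AHCA_METHODS = (
    "average",
    "single",
    "complete",
    "centroid",
    "median",
    "ward",
    "flexible_beta",
    "mcquitty",
)

_SQE_METHODS = ("centroid", "median", "ward")


@dataclass
class Dendrogram:
    """Ordered merge table.

    ``merges`` has n-1 rows (child_a, child_b, height, new_size) in scipy
    convention: leaves are 0..n-1, the cluster created by merge row i is
    n+i.  ``direction`` records whether the tree was built bottom-up
    (agglomerative) or top-down (divisive, re-expressed as merges).
    Inversions (height decreases, possible for centroid/median linkage) are
    recorded, not raised.
    """

    merges: np.ndarray
    direction: str
    method: str
    distance: DistanceSpec
    inversions: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.merges, columns=["child_a", "child_b", "height", "size"]
        )
        df[["child_a", "child_b", "size"]] = df[
            ["child_a", "child_b", "size"]
        ].astype(int)
        return df

    def leaf_order(self) -> list:
        """Left-to-right case order of a crossing-free tree drawing."""
        n = self.n_leaves
        children = {}
        for step, (a, b, _, _) in enumerate(self.merges):
            children[n + step] = (int(a), int(b))
        order = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                a, b = children[node]
                stack.extend([b, a])
        return order

    def banner_data(self) -> pd.DataFrame:
        """Plot-ready banner data: adjacent case pairs in leaf order with
        the height of the merge that first joins them."""
        n = self.n_leaves
        order = self.leaf_order()
        # replay the merges to find the height joining each leaf pair
        join_height = {}
        members = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            sa, sb = members.pop(int(a)), members.pop(int(b))
            for i in sa:
                for j in sb:
                    join_height[(i, j)] = join_height[(j, i)] = h
            members[n + step] = sa | sb
        rows = [
            {
                "case": order[i],
                "next_case": order[i + 1],
                "height": join_height[(order[i], order[i + 1])],
            }
            for i in range(n - 1)
        ]
        return pd.DataFrame(rows)


def _lw_coefficients(method: str, ni: float, nj: float, nk: float, beta: float):
    """Lance–Williams (alpha_i, alpha_j, beta, gamma) for merging i,j vs k."""
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if method == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if method == "centroid":
        s = ni + nj
        return ni / s, nj / s, -ni * nj / s**2, 0.0
    if method == "median":
        return 0.5, 0.5, -0.25, 0.0
    if method == "ward":
        t = ni + nj + nk
        return (ni + nk) / t, (nj + nk) / t, -nk / t, 0.0
    if method == "flexible_beta":
        return (1 - beta) / 2, (1 - beta) / 2, beta, 0.0
    raise ValueError(f"unknown linkage method {method!r}")


def _as_distance_matrix(data, spec: DistanceSpec) -> np.ndarray:
    if isinstance(data, DataMatrix):
        return pairwise_distances(data, spec)
    D = np.asarray(data, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix or a DataMatrix")
    return D.copy()


def ahca(
    data,
    method: str = "ward",
    spec: DistanceSpec = DistanceSpec("squared_euclidean"),
    beta: float = -0.25,
) -> Dendrogram:
    """Agglomerative hierarchical clustering by the Lance–Williams recurrence.

    ``data`` may be a (standardized) DataMatrix or a precomputed square
    distance matrix.  Among equal minimum inter-cluster distances the pair
    with lexicographically smallest slot indices merges first.
    """
    if method not in AHCA_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {AHCA_METHODS}")
    if method in _SQE_METHODS and spec.name != "squared_euclidean":
        warnings.warn(
            f"{method} linkage assumes squared Euclidean distances; "
            f"got {spec.name}",
            stacklevel=2,
        )
    D = _as_distance_matrix(data, spec)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    n = D.shape[0]
    D = D.astype(float)
    np.fill_diagonal(D, np.inf)

    sizes = np.ones(n)
    cluster_id = np.arange(n)  # scipy-style id currently held by each slot
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    inversions = []
    last_h = -np.inf
    work = D.copy()

    for step in range(n - 1):
        # lexicographically-first argmin over the active upper triangle
        flat = np.argmin(work)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d_ij = work[i, j]
        ni, nj = sizes[i], sizes[j]
        a, b = cluster_id[i], cluster_id[j]
        child_a, child_b = (a, b) if a <= b else (b, a)
        merges[step] = (child_a, child_b, d_ij, ni + nj)
        if d_ij < last_h - 1e-12:
            inversions.append(step)
        last_h = max(last_h, d_ij)

        ks = np.where(active)[0]
        ks = ks[(ks != i) & (ks != j)]
        if ks.size:
            dik = work[i, ks]
            djk = work[j, ks]
            if method in ("single", "complete", "average", "mcquitty"):
                ai, aj, bb, g = _lw_coefficients(method, ni, nj, 1.0, beta)
                new = ai * dik + aj * djk + bb * d_ij + g * np.abs(dik - djk)
            elif method in ("centroid", "median", "flexible_beta"):
                ai, aj, bb, g = _lw_coefficients(method, ni, nj, 1.0, beta)
                new = ai * dik + aj * djk + bb * d_ij
            else:  # ward: coefficients depend on nk
                nk = sizes[ks]
                t = ni + nj + nk
                new = ((ni + nk) * dik + (nj + nk) * djk - nk * d_ij) / t
            work[i, ks] = new
            work[ks, i] = new
        # retire slot j, keep merged cluster in slot i (the smaller slot)
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        work[i, i] = np.inf
        sizes[i] = ni + nj
        cluster_id[i] = n + step

    return Dendrogram(
        merges=merges,
        direction="agglomerative",
        method=method,
        distance=spec,
        inversions=inversions,
    )


def _splinter_split(D: np.ndarray, members: np.ndarray):
    """Kaufman–Rousseeuw splinter procedure on one cluster.

    Seed = member with maximal average dissimilarity to the others; members
    then defect one at a time (largest positive gain first) while their
    average dissimilarity to the splinter group is smaller than to the rest.
    """
    m = members.size
    sub = D[np.ix_(members, members)]
    avg = sub.sum(axis=1) / (m - 1)
    in_splinter = np.zeros(m, dtype=bool)
    in_splinter[int(np.argmax(avg))] = True
    while True:
        rest = ~in_splinter
        n_rest = rest.sum()
        if n_rest <= 1:
            break
        # for each remaining object: avg distance to rest-minus-self vs splinter
        d_to_spl = sub[:, in_splinter].mean(axis=1)
        d_to_rest = (sub[:, rest].sum(axis=1) - 0.0) / np.maximum(n_rest - 1, 1)
        gain = np.where(rest, d_to_rest - d_to_spl, -np.inf)
        best = int(np.argmax(gain))
        if gain[best] > 1e-12:
            in_splinter[best] = True
        else:
            break
    return members[in_splinter], members[~in_splinter]


def diana(
    data, spec: DistanceSpec = DistanceSpec("squared_euclidean")
) -> Dendrogram:
    """Divisive hierarchical clustering (DIANA).

    At each step the cluster with the largest diameter is split by the
    splinter procedure; the split height is that diameter.  The resulting
    split sequence is reversed into an agglomerative-style merge table
    (heights nondecreasing), so :func:`cut_tree` applies unchanged: cutting
    at k reproduces the state after k-1 divisions.
    """
    D = _as_distance_matrix(data, spec)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    n = D.shape[0]
    Dz = D.copy()
    np.fill_diagonal(Dz, 0.0)

    def diameter(members):
        if members.size < 2:
            return 0.0
        return float(Dz[np.ix_(members, members)].max())

    clusters = [np.arange(n)]
    splits = []  # (members_a, members_b, height) in split order
    while len(clusters) < n:
        diams = [diameter(c) for c in clusters]
        # largest diameter; ties broken by smallest leading member
        order = sorted(
            range(len(clusters)), key=lambda i: (-diams[i], int(clusters[i][0]))
        )
        idx = order[0]
        target = clusters.pop(idx)
        if target.size == 2:
            a, b = np.array([target[0]]), np.array([target[1]])
        else:
            a, b = _splinter_split(Dz, target)
        splits.append((a, b, diams[idx]))
        clusters.extend([a, b])

    # reverse splits into merges; assign scipy-style ids bottom-up
    merges = np.empty((n - 1, 4))
    id_of = {}  # frozenset of members -> cluster id
    for i in range(n):
        id_of[frozenset([i])] = i
    for step, (a, b, h) in enumerate(reversed(splits)):
        ia = id_of[frozenset(a.tolist())]
        ib = id_of[frozenset(b.tolist())]
        ca, cb = (ia, ib) if ia <= ib else (ib, ia)
        merges[step] = (ca, cb, h, a.size + b.size)
        id_of[frozenset(a.tolist()) | frozenset(b.tolist())] = n + step
    return Dendrogram(
        merges=merges, direction="divisive", method="diana", distance=spec
    )


def cut_tree(dend: Dendrogram, k: int) -> Partition:
    """Partition into k clusters after exactly n-k merges (k-1 divisions).

    Labels are renumbered 1..k by first case appearance.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    members = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = dend.merges[step]
        a, b = int(a), int(b)
        ma = members.pop(a)
        mb = members.pop(b)
        members[n + step] = ma + mb
    lab = np.empty(n, dtype=int)
    for cid, mem in members.items():
        for i in mem:
            lab[i] = cid
    # renumber 1..k by first case appearance
    mapping = {}
    out = np.empty(n, dtype=int)
    nxt = 1
    for i in range(n):
        if lab[i] not in mapping:
            mapping[lab[i]] = nxt
            nxt += 1
        out[i] = mapping[lab[i]]
    return Partition(out, k=len(members))


def total_ss(data: DataMatrix) -> float:
    """Total sum of squared deviations from the grand centroid."""
    X = data.values
    return float(((X - X.mean(axis=0)) ** 2).sum())


def wss_series(data: DataMatrix, partitions) -> pd.DataFrame:
    """Total within-cluster sum of squares for each partition.

    TotalWSS(k) = sum over clusters of squared Euclidean deviations from the
    cluster centroid; the elbow of this series against k is the classical
    aid for choosing the number of clusters.
    """
    X = data.values
    rows = []
    for part in partitions:
        wss = 0.0
        for c in range(1, part.k + 1):
            mask = part.labels == c
            sub = X[mask]
            wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
        rows.append({"k": part.k, "total_wss": wss})
    return pd.DataFrame(rows)
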