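"""Simulation-null validation and cross-solution agreement.

Three tools for judging whether a cluster solution reflects real structure:

* **MORI** — measure of relative improvement.  The observed quality
  coefficients are compared with their mean across clusterings of simulated
  random data: multivariate normal samples whose intercorrelations match the
  observed variables, generated as ``x = A z`` from the varimax-rotated full
  principal-component loading matrix A (so ``A A' = R``).  For a QC with
  ideal value ``best`` and null mean ``rbar``, MORI = (obs - rbar)/(best -
  rbar); for HCmean, where smaller is better with ideal 0, MORI =
  (rbar - obs)/rbar.  Zero means "no better than correlation-matched
  noise", values around 0.3 a medium-sized, above 0.5 a strong dominance.
* **Centroid matching** — the full ASED matrix between two solutions'
  centroids, with a minimum-total-ASED one-to-one assignment when both have
  the same number of clusters.
* **Exacon-style CMR** — the two-way frequency table of two partitions with
  each cell's count divided by the harmonic mean of its row and column
  totals; matched-pair CMR near 1 means the clusters contain essentially
  the same cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .core import (
    ClusterSolution,
    DataMatrix,
    DistanceSpec,
    Partition,
    pairwise_distances,
    standardize,
)
from .quality import QCSet, qc_set

__all__ = [
    "LoadingMatrix",
    "MoriReport",
    "CrossTab",
    "varimax_loadings",
    "simulate_null",
    "mori",
    "centroid_match",
    "exacon_cmr",
    "write_loading_matrix",
    "read_loading_matrix",
]


@dataclass
class LoadingMatrix:
    """Varimax-rotated full principal-component loading matrix A (p x p).

    All components are retained, so ``A A'`` reproduces the observed
    correlation matrix exactly (orthogonal rotation preserves it).
    """

    A: np.ndarray
    var_names: list | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("loading matrix must be square (all components kept)")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def implied_correlation(self) -> np.ndarray:
        return self.A @ self.A.T


def varimax_loadings(data: DataMatrix) -> LoadingMatrix:
    """All-components PCA of the correlation matrix, varimax-rotated.

    With every component retained the rows of the unrotated loading matrix
    have unit communality, so Kaiser row-normalization is a no-op and the
    rotated A still satisfies ``A A' = R``.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    X = data.values
    if np.isnan(X).any():
        raise ValueError("missing values present; run preprocessing first")
    R = np.corrcoef(X, rowvar=False)
    if data.p < 2:
        raise ValueError("need at least 2 variables")
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[-1] < 1e-10:
        raise ValueError("correlation matrix is rank-deficient")
    A0 = V * np.sqrt(w)[None, :]
    A, _ = rotate_factors(A0, "varimax")
    # sign convention: make each column's largest-magnitude loading positive
    for j in range(A.shape[1]):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]
    return LoadingMatrix(A=A, var_names=list(data.var_names))


def simulate_null(
    loadings: LoadingMatrix, n: int, seed=None, var_names=None
) -> DataMatrix:
    """Correlated-normal null sample: x = A z with z iid standard normal.

    Columns are re-standardized (n-1 denominator) so null replicates enter
    the clustering pipeline exactly like the observed standardized data.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, loadings.p))
    X = Z @ loadings.A.T
    names = var_names or loadings.var_names
    dm = DataMatrix(values=X, var_names=list(names) if names else None)
    return standardize(dm)


@dataclass
class MoriQC:
    name: str
    observed: float
    null_mean: float
    null_sd: float
    mori: float | None  # None when the null mean sits at the ideal value


@dataclass
class MoriReport:
    qcs: dict  # name -> MoriQC
    reps: int
    seed: object
    k: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "QC": q.name,
                "observed": q.observed,
                "null_mean": q.null_mean,
                "null_sd": q.null_sd,
                "MORI": q.mori,
            }
            for q in self.qcs.values()
        ]
        return pd.DataFrame(rows).set_index("QC")


#: per-QC ideal values used in the relative-improvement denominator
_MORI_IDEAL = {"EESS%": 100.0, "silhouette": 1.0, "XBmod": 2.0, "HCmean": 0.0}


def _mori_one(name: str, obs: float, rbar: float) -> float | None:
    best = _MORI_IDEAL[name]
    if name == "HCmean":  # smaller is better, ideal 0
        if rbar == 0:
            return None
        return (rbar - obs) / rbar
    denom = best - rbar
    if denom == 0:
        return None
    return (obs - rbar) / denom


def mori(
    data: DataMatrix,
    clusterer,
    k: int,
    reps: int = 25,
    seed=None,
    loadings: LoadingMatrix | None = None,
    observed_qc: QCSet | None = None,
) -> MoriReport:
    """Relative improvement of observed QCs over a simulated null.

    ``clusterer`` is a callable ``(DataMatrix, seed) -> Partition`` that
    reproduces the observed pipeline (same algorithm, same k, standardized
    input).  Each of ``reps`` replicates draws a correlation-matched normal
    sample of the observed size, clusters it with a fresh seed spawned from
    the master seed, and records its QCSet; MORI is then computed per QC.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    sdata = data if data.standardized else standardize(data)
    if loadings is None:
        loadings = varimax_loadings(sdata)
    if observed_qc is None:
        D = pairwise_distances(sdata, DistanceSpec("ased"))
        part = clusterer(sdata, seed)
        observed_qc = qc_set(sdata, part, D=D)
    null_vals = {name: [] for name in _MORI_IDEAL}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    for child in children:
        # plain ints so any clusterer signature can consume them
        gen_seed, clu_seed = (int(s) % 2**31 for s in child.generate_state(2))
        null = simulate_null(loadings, sdata.n, seed=gen_seed)
        part = clusterer(null, clu_seed)
        D0 = pairwise_distances(null, DistanceSpec("ased"))
        q = qc_set(null, part, D=D0)
        null_vals["EESS%"].append(q.EESS_pct)
        null_vals["XBmod"].append(q.XBmod)
        null_vals["HCmean"].append(q.HCmean)
        null_vals["silhouette"].append(q.mean_silhouette)
    obs_map = {
        "EESS%": observed_qc.EESS_pct,
        "XBmod": observed_qc.XBmod,
        "HCmean": observed_qc.HCmean,
        "silhouette": observed_qc.mean_silhouette,
    }
    out = {}
    for name, vals in null_vals.items():
        vals = np.asarray(vals, float)
        rbar = float(vals.mean())
        out[name] = MoriQC(
            name=name,
            observed=obs_map[name],
            null_mean=rbar,
            null_sd=float(vals.std(ddof=1)),
            mori=_mori_one(name, obs_map[name], rbar),
        )
    return MoriReport(qcs=out, reps=reps, seed=seed, k=k)


# ------------------------------------------------------- centroid matching


@dataclass
class CentroidMatch:
    ased: np.ndarray  # k_a x k_b full ASED matrix
    pairs: list  # (cluster_a, cluster_b, ased) sorted by ased
    total: float

    def matched_aseds(self) -> list:
        return [d for *_, d in self.pairs]


def centroid_match(sol_a, sol_b) -> CentroidMatch:
    """Full inter-centroid ASED matrix plus the optimal one-to-one matching.

    Accepts ClusterSolutions or bare centroid matrices on the same
    variables.  When both solutions have the same number of clusters the
    pairing minimizes the total ASED (optimal assignment); matched
    distances are reported in increasing order.
    """
    Ca = sol_a.centroids if isinstance(sol_a, ClusterSolution) else np.asarray(sol_a)
    Cb = sol_b.centroids if isinstance(sol_b, ClusterSolution) else np.asarray(sol_b)
    if Ca.shape[1] != Cb.shape[1]:
        raise ValueError("solutions live on different variable sets")
    p = Ca.shape[1]
    D = cdist(Ca, Cb, "sqeuclidean") / p
    pairs = []
    total = np.nan
    if Ca.shape[0] == Cb.shape[0]:
        rows, cols = linear_sum_assignment(D)
        pairs = sorted(
            [(int(r) + 1, int(c) + 1, float(D[r, c])) for r, c in zip(rows, cols)],
            key=lambda t: t[2],
        )
        total = float(D[rows, cols].sum())
    return CentroidMatch(ased=D, pairs=pairs, total=total)


@dataclass
class CrossTab:
    table: pd.DataFrame  # contingency counts, rows = partition a
    cmr: pd.DataFrame
    pairs: list = field(default_factory=list)  # (a, b, cmr) matched pairs


def exacon_cmr(part_a: Partition, part_b: Partition, match: bool = True) -> CrossTab:
    """Two-way frequency table with cell matching ratios.

    CMR(a, b) = n_ab / harmonic_mean(row total, column total)
             = n_ab * (r_a + c_b) / (2 * r_a * c_b).
    With ``match`` true, a one-to-one pairing maximizing total CMR is
    reported (all pairings have CMR in [0, 1]).
    """
    if part_a.n != part_b.n:
        raise ValueError("partitions cover different case sets")
    tab = pd.crosstab(
        pd.Series(part_a.labels, name="a"), pd.Series(part_b.labels, name="b")
    ).reindex(
        index=range(1, part_a.k + 1), columns=range(1, part_b.k + 1), fill_value=0
    )
    counts = tab.to_numpy(float)
    r = counts.sum(axis=1, keepdims=True)
    c = counts.sum(axis=0, keepdims=True)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("empty cluster in one of the partitions")
    cmr = counts * (r + c) / (2.0 * r * c)
    cmr_df = pd.DataFrame(cmr, index=tab.index, columns=tab.columns)
    pairs = []
    if match and part_a.k == part_b.k:
        rows, cols = linear_sum_assignment(-cmr)
        pairs = sorted(
            [(int(rr) + 1, int(cc) + 1, float(cmr[rr, cc])) for rr, cc in zip(rows, cols)],
            key=lambda t: -t[2],
        )
    return CrossTab(table=tab, cmr=cmr_df, pairs=pairs)


# ------------------------------------------------------- loading file I/O


def write_loading_matrix(loadings: LoadingMatrix, path) -> None:
    """Whitespace-separated p x p loading matrix, one row per variable."""
    np.savetxt(path, loadings.A, fmt="%.10f")


def read_loading_matrix(path) -> LoadingMatrix:
    A = np.loadtxt(path)
    if A.ndim == 1:
        A = A.reshape(1, -1)
    return LoadingMatrix(A=A)
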