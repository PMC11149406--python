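"""Cluster-quality coefficients for person-oriented typologies.

The suite evaluates a partition of standardized cases by homogeneity and
separation:

* **HC** — per-cluster homogeneity coefficient: the mean pairwise ASED
  within a cluster, equivalently ``2·WSS_c / (p·(n_c − 1))``.  0 for a
  cluster of identical members; about 2 for a random standardized sample
  (exactly 2 for the whole sample when the sd uses the n−1 denominator).
  ``HCmean`` is the size-weighted mean over clusters.
* **EESS%** — explained error sum of squares percent,
  ``100·(T − TotalWSS)/T``: the multivariate generalization of the
  eta-squared effect size.
* **XBmod** — a modified Xie–Beni-style separation measure, computed here
  as the minimum inter-centroid ASED minus HCmean, so overlapping solutions
  go negative and a value above 0.5 indicates clear separation.  (The
  originating software does not publish its exact formula; this
  reconstruction is isolated in :func:`xbmod` for easy replacement and its
  rationale is documented in the methods note.)
* **Silhouette** — Rousseeuw's mean silhouette width (singletons scored 0).
* **Homogeneity percentages** — percent of cases in clusters with HC
  strictly below 0.10 / 0.20 / 0.30 / 0.50.

Conventional acceptability thresholds: EESS% > 70, XBmod > 0.50,
HCmean < 0.50 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import DataMatrix, Partition

__all__ = [
    "QCSet",
    "PatternTable",
    "cluster_hc",
    "eess_pct",
    "xbmod",
    "silhouette_mean",
    "homogeneity_percentages",
    "acceptability",
    "pattern_table",
    "qc_set",
    "qc_table",
]

HOM_THRESHOLDS = (0.10, 0.20, 0.30, 0.50)
DEFAULT_ACCEPT = {"eess_min": 70.0, "xbmod_min": 0.50, "hcmean_max": 0.50}


@dataclass
class QCSet:
    """Quality coefficients of one cluster solution."""

    k: int
    EESS_pct: float
    XBmod: float
    HCmean: float
    HCmin: float
    HCmax: float
    mean_silhouette: float | None = None
    Hom10: float = np.nan
    Hom20: float = np.nan
    Hom30: float = np.nan
    Hom50: float = np.nan
    TotalWSS: float = np.nan

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "EESS%": self.EESS_pct,
            "XBmod": self.XBmod,
            "HCmean": self.HCmean,
            "HCmin": self.HCmin,
            "HCmax": self.HCmax,
            "silhouette": self.mean_silhouette,
            "Hom10": self.Hom10,
            "Hom20": self.Hom20,
            "Hom30": self.Hom30,
            "Hom50": self.Hom50,
            "TotalWSS": self.TotalWSS,
        }


def _wss_per_cluster(X: np.ndarray, part: Partition) -> np.ndarray:
    out = np.zeros(part.k)
    for c in range(1, part.k + 1):
        sub = X[part.labels == c]
        out[c - 1] = ((sub - sub.mean(axis=0)) ** 2).sum()
    return out


def cluster_hc(data: DataMatrix, part: Partition):
    """Per-cluster HC plus (HCmean, HCmin, HCmax).

    HC_c = mean pairwise ASED within cluster c = 2·WSS_c/(p·(n_c−1));
    singletons score 0.  HCmean is weighted by cluster size.
    """
    X = data.values
    p = data.p
    sizes = part.sizes
    wss = _wss_per_cluster(X, part)
    hc = np.zeros(part.k)
    nz = sizes > 1
    hc[nz] = 2.0 * wss[nz] / (p * (sizes[nz] - 1))
    hcmean = float((sizes * hc).sum() / sizes.sum())
    return hc, hcmean, float(hc.min()), float(hc.max())


def eess_pct(data: DataMatrix, part: Partition) -> float:
    """Explained error sum of squares percent: 100·(T − WSS)/T."""
    X = data.values
    T = float(((X - X.mean(axis=0)) ** 2).sum())
    if T <= 0:
        raise ValueError("total sum of squares is zero")
    wss = float(_wss_per_cluster(X, part).sum())
    return 100.0 * (T - wss) / T


def xbmod(data: DataMatrix, part: Partition) -> float:
    """Separation: minimum inter-centroid ASED minus HCmean.

    Negative when the closest pair of centroids is nearer than the average
    within-cluster spread — the signature of an overlapping solution.
    """
    if part.k < 2:
        raise ValueError("XBmod needs k >= 2")
    X = data.values
    cent = np.array([X[part.labels == c].mean(axis=0) for c in range(1, part.k + 1)])
    d = cdist(cent, cent, "sqeuclidean") / data.p
    np.fill_diagonal(d, np.inf)
    _, hcmean, _, _ = cluster_hc(data, part)
    return float(d.min() - hcmean)


def silhouette_mean(D: np.ndarray, part: Partition) -> float:
    """Mean Rousseeuw silhouette width from a precomputed distance matrix.

    s_i = (b_i − a_i)/max(a_i, b_i) with a_i the mean distance to own-cluster
    peers and b_i the smallest mean distance to another cluster; members of
    singleton clusters score 0.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    labels = part.labels
    sizes = part.sizes
    s = np.zeros(n)
    masks = [labels == c for c in range(1, part.k + 1)]
    sums = np.stack([D[:, m].sum(axis=1) for m in masks], axis=1)  # n x k
    for i in range(n):
        c = labels[i] - 1
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, cc] / sizes[cc] for cc in range(part.k) if cc != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def homogeneity_percentages(hc: np.ndarray, sizes: np.ndarray, n: int | None = None):
    """(Hom10, Hom20, Hom30, Hom50): % of cases in clusters with HC < T.

    Strict inequality at each threshold.
    """
    hc = np.asarray(hc, float)
    sizes = np.asarray(sizes)
    if n is None:
        n = int(sizes.sum())
    out = tuple(
        float(100.0 * sizes[hc < t].sum() / n) for t in HOM_THRESHOLDS
    )
    return out


def acceptability(qc: QCSet, thresholds: dict | None = None) -> dict:
    """Strict acceptability flags: EESS% > 70, XBmod > 0.50, HCmean < 0.50."""
    t = dict(DEFAULT_ACCEPT)
    if thresholds:
        t.update(thresholds)
    flags = {
        "eess_ok": qc.EESS_pct > t["eess_min"],
        "xbmod_ok": qc.XBmod > t["xbmod_min"],
        "hcmean_ok": qc.HCmean < t["hcmean_max"],
    }
    flags["acceptable"] = all(flags.values())
    return flags


# ------------------------------------------------------------- patterns

#: half-open z-score bands for the centroid pattern codes; the band of a
#: positive mean z maps to "(H)", "H", "H+", ... and symmetrically to "L".
PATTERN_BANDS = (
    (0.25, "."),
    (0.50, "({s})"),
    (1.00, "{s}"),
    (1.50, "{s}+"),
    (2.00, "{s}++"),
    (2.50, "{s}+++"),
    (np.inf, "{s}++++"),
)


def pattern_code(z: float, bands=PATTERN_BANDS) -> str:
    """Code one standardized cluster mean: '.' near zero, (H)/(L) mild,
    H/L marked, with a '+' per additional half sd up to '++++'."""
    s = "H" if z >= 0 else "L"
    a = abs(z)
    for upper, fmt in bands:
        if a < upper:
            return fmt.format(s=s)
    return bands[-1][1].format(s=s)  # pragma: no cover


@dataclass
class PatternTable:
    codes: pd.DataFrame  # clusters x variables, string codes
    means: pd.DataFrame  # clusters x variables, standardized means
    sizes: np.ndarray
    hc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.codes.copy()
        df["CLsize"] = self.sizes
        df["HC"] = np.round(self.hc, 2)
        return df


def pattern_table(data: DataMatrix, part: Partition) -> PatternTable:
    """Pattern of standardized means per cluster with CLsize and HC columns."""
    X = data.values
    means = np.array([X[part.labels == c].mean(axis=0) for c in range(1, part.k + 1)])
    codes = np.vectorize(pattern_code)(means)
    idx = [f"CL{c}" for c in range(1, part.k + 1)]
    hc, *_ = cluster_hc(data, part)
    return PatternTable(
        codes=pd.DataFrame(codes, index=idx, columns=data.var_names),
        means=pd.DataFrame(means, index=idx, columns=data.var_names),
        sizes=part.sizes,
        hc=hc,
    )


def qc_set(data: DataMatrix, part: Partition, D: np.ndarray | None = None) -> QCSet:
    """Assemble the full QCSet for one partition of standardized data."""
    hc, hcmean, hcmin, hcmax = cluster_hc(data, part)
    wss = float(_wss_per_cluster(data.values, part).sum())
    homs = homogeneity_percentages(hc, part.sizes)
    sil = None
    if D is not None and part.k >= 2:
        sil = silhouette_mean(D, part)
    xb = xbmod(data, part) if part.k >= 2 else np.nan
    return QCSet(
        k=part.k,
        EESS_pct=eess_pct(data, part),
        XBmod=xb,
        HCmean=hcmean,
        HCmin=hcmin,
        HCmax=hcmax,
        mean_silhouette=sil,
        Hom10=homs[0],
        Hom20=homs[1],
        Hom30=homs[2],
        Hom50=homs[3],
        TotalWSS=wss,
    )


def qc_table(qcs) -> pd.DataFrame:
    """Summary table of QCs across solutions (rows = k)."""
    return pd.DataFrame([q.as_dict() for q in qcs]).set_index("k")
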