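"""Item truncation, scale construction, outlier screening and reliability.

The preprocessing pipeline mirrors common practice with Likert-derived
psychological scales: heavily right-skewed items are truncated (top
categories fused), scale scores are formed as the mean of the usable items
under a per-scale missing-item allowance, cases incomplete on the analysis
variables are dropped, and a nearest-neighbour ASED screen flags multivariate
outliers before clustering.  Scale reliability is summarised by Cronbach's
alpha (with Feldt's exact F interval) and McDonald's omega from a one-factor
maximum-likelihood fit (with a seeded percentile-bootstrap interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataMatrix, DistanceSpec, pairwise_distances

__all__ = [
    "LikertItemSet",
    "ReliabilityReport",
    "OutlierReport",
    "truncate_items",
    "build_scales",
    "complete_cases",
    "nn_outliers",
    "cronbach_alpha",
    "mcdonald_omega",
    "reliability",
]


@dataclass
class LikertItemSet:
    """Item-level response matrix with a scale map.

    ``items`` is n x m with NaN for missing responses; every non-missing
    entry must lie in ``[lo, hi]``.  ``scale_map`` assigns named scales to
    item column indices; ``max_missing`` gives, per scale, how many items may
    be missing while the scale score is still formed from the usable items.
    """

    items: np.ndarray
    lo: float
    hi: float
    scale_map: dict
    max_missing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        vals = self.items[~np.isnan(self.items)]
        if vals.size and (vals.min() < self.lo or vals.max() > self.hi):
            raise ValueError(f"item values outside [{self.lo}, {self.hi}]")
        m = self.items.shape[1]
        for name, cols in self.scale_map.items():
            if any(c < 0 or c >= m for c in cols):
                raise ValueError(f"scale {name!r} references nonexistent items")

    @property
    def n(self) -> int:
        return self.items.shape[0]

    def scale_items(self, name: str) -> np.ndarray:
        return self.items[:, list(self.scale_map[name])]


@dataclass
class ScaleReliability:
    scale: str
    usable_cases: int
    alpha: float
    alpha_ci95: tuple
    omega: float | None
    omega_ci95: tuple | None
    loadings: np.ndarray | None = None
    uniquenesses: np.ndarray | None = None
    warning: str | None = None


@dataclass
class ReliabilityReport:
    scales: dict  # name -> ScaleReliability

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, r in self.scales.items():
            rows.append(
                {
                    "scale": name,
                    "usable_cases": r.usable_cases,
                    "alpha": r.alpha,
                    "alpha_lo": r.alpha_ci95[0],
                    "alpha_hi": r.alpha_ci95[1],
                    "omega": r.omega,
                    "omega_lo": None if r.omega_ci95 is None else r.omega_ci95[0],
                    "omega_hi": None if r.omega_ci95 is None else r.omega_ci95[1],
                }
            )
        return pd.DataFrame(rows).set_index("scale")


@dataclass
class OutlierReport:
    nn_ased: np.ndarray
    flags: np.ndarray
    threshold: float
    neighbours: int

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def truncate_items(itemset: LikertItemSet, rules: dict) -> LikertItemSet:
    """Fuse top response categories: values above ``cap`` are set to ``cap``.

    ``rules`` maps scale name -> cap value (e.g. anxiety items capped at 3 so
    responses of 4 and 5 become 3).  Missing entries are untouched; the new
    upper range is recorded.
    """
    items = itemset.items.copy()
    for name, cap in rules.items():
        if name not in itemset.scale_map:
            raise ValueError(f"rule references unknown scale {name!r}")
        if not (itemset.lo <= cap <= itemset.hi):
            raise ValueError(f"cap {cap} outside item range [{itemset.lo}, {itemset.hi}]")
        cols = list(itemset.scale_map[name])
        block = items[:, cols]
        with np.errstate(invalid="ignore"):
            block[block > cap] = cap
        items[:, cols] = block
    new_hi = float(np.nanmax(items)) if np.isfinite(np.nanmax(items)) else itemset.hi
    return LikertItemSet(
        items=items,
        lo=itemset.lo,
        hi=max(new_hi, itemset.lo),
        scale_map=dict(itemset.scale_map),
        max_missing=dict(itemset.max_missing),
    )


def build_scales(itemset: LikertItemSet) -> DataMatrix:
    """Scale scores as the mean of usable items under the missing allowance.

    A scale score is the mean of the case's non-missing items when at most
    ``max_missing[scale]`` items are missing (default 0), otherwise missing.
    """
    if not itemset.scale_map:
        raise ValueError("empty scale map")
    cols = []
    names = []
    for name, idx in itemset.scale_map.items():
        block = itemset.scale_items(name)
        n_miss = np.isnan(block).sum(axis=1)
        allow = int(itemset.max_missing.get(name, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            score = np.nanmean(block, axis=1)
        score[n_miss > allow] = np.nan
        if np.isnan(score).all():
            raise ValueError(f"scale {name!r} has zero usable items for every case")
        cols.append(score)
        names.append(name)
    return DataMatrix(values=np.column_stack(cols), var_names=names)


def complete_cases(data: DataMatrix, var_names=None) -> DataMatrix:
    """Drop cases with any missing value on the requested variables."""
    sub = data if var_names is None else data.select(list(var_names))
    keep = ~np.isnan(sub.values).any(axis=1)
    if not keep.any() or keep.sum() < 2:
        raise ValueError("fewer than 2 complete cases remain")
    out = data if var_names is None else sub
    return DataMatrix(
        values=out.values[keep],
        case_ids=[cid for cid, k in zip(out.case_ids, keep) if k],
        var_names=list(out.var_names),
        standardized=out.standardized,
        standardization_params=out.standardization_params,
    )


def nn_outliers(
    data: DataMatrix, threshold: float = 0.7, neighbours: int = 1
) -> OutlierReport:
    """Nearest-neighbour ASED residual screen.

    For each case, the mean ASED to its ``neighbours`` nearest other cases;
    cases whose value exceeds ``threshold`` (default 0.7, on standardized
    variables) are flagged as multivariate outliers.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not data.standardized:
        warnings.warn("nn_outliers expects standardized data", stacklevel=2)
    D = pairwise_distances(data, DistanceSpec("ased"))
    np.fill_diagonal(D, np.inf)
    k = int(neighbours)
    if k < 1 or k > data.n - 1:
        raise ValueError("neighbours out of range")
    part = np.partition(D, k - 1, axis=1)[:, :k]
    nn = part.mean(axis=1)
    return OutlierReport(
        nn_ased=nn, flags=nn > threshold, threshold=threshold, neighbours=k
    )


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha m/(m-1) * (1 - sum(item var)/var(total)) on complete rows."""
    X = np.asarray(items, float)
    X = X[~np.isnan(X).any(axis=1)]
    m = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    return float(m / (m - 1) * (1 - item_var / total_var))


def _one_factor_ml(R: np.ndarray, n_obs: int):
    """One-factor ML loadings/uniquenesses from a correlation matrix."""
    from statsmodels.multivariate.factor import Factor

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = Factor(corr=R, n_factor=1, method="ml", nobs=n_obs).fit()
    lam = np.asarray(fit.loadings).ravel()
    if lam.sum() < 0:  # sign indeterminacy
        lam = -lam
    theta = 1.0 - lam**2
    return lam, theta


def mcdonald_omega(items: np.ndarray) -> tuple:
    """McDonald's omega (sum lambda)^2 / ((sum lambda)^2 + sum theta).

    Items are standardized for the factor fit (loadings on the correlation
    metric), the convention of common reliability software.
    """
    X = np.asarray(items, float)
    X = X[~np.isnan(X).any(axis=1)]
    R = np.corrcoef(X, rowvar=False)
    if np.allclose(R, 1.0):  # items are copies of one vector
        m = R.shape[0]
        return 1.0, np.ones(m), np.zeros(m)
    lam, theta = _one_factor_ml(R, X.shape[0])
    s = lam.sum()
    omega = s**2 / (s**2 + theta.sum())
    return float(omega), lam, theta


def _feldt_ci(alpha: float, n: int, m: int, level: float = 0.95) -> tuple:
    """Feldt's exact F interval for Cronbach's alpha."""
    df1 = n - 1
    df2 = (n - 1) * (m - 1)
    a = 1 - level
    lo = 1 - (1 - alpha) * stats.f.ppf(1 - a / 2, df1, df2)
    hi = 1 - (1 - alpha) * stats.f.ppf(a / 2, df1, df2)
    return float(lo), float(hi)


def reliability(
    itemset: LikertItemSet, n_boot: int = 1000, seed: int | None = None
) -> ReliabilityReport:
    """Per-scale alpha and omega with 95% intervals on listwise-complete cases.

    Alpha CI: Feldt's exact F method.  Omega CI: seeded percentile bootstrap
    (``n_boot`` resamples).  A non-convergent factor fit downgrades the scale
    to alpha-only with a warning record.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in itemset.scale_map:
        block = itemset.scale_items(name)
        X = block[~np.isnan(block).any(axis=1)]
        n, m = X.shape
        if m < 2:
            raise ValueError(f"scale {name!r} needs >= 2 items")
        if n < 3:
            raise ValueError(f"scale {name!r} needs >= 3 complete cases")
        alpha = cronbach_alpha(X)
        a_ci = _feldt_ci(alpha, n, m)
        omega = om_ci = lam = theta = None
        warn = None
        try:
            omega, lam, theta = mcdonald_omega(X)
            boots = []
            for _ in range(n_boot):
                idx = rng.integers(0, n, n)
                try:
                    boots.append(mcdonald_omega(X[idx])[0])
                except Exception:
                    continue
            if len(boots) >= max(20, n_boot // 2):
                om_ci = tuple(np.percentile(boots, [2.5, 97.5]))
            else:
                warn = "omega bootstrap unstable; interval omitted"
        except Exception as exc:  # non-convergent factor fit
            warn = f"one-factor ML fit failed ({exc}); omega omitted"
        out[name] = ScaleReliability(
            scale=name,
            usable_cases=n,
            alpha=alpha,
            alpha_ci95=a_ci,
            omega=omega,
            omega_ci95=om_ci,
            loadings=lam,
            uniquenesses=theta,
            warning=warn,
        )
    return ReliabilityReport(scales=out)
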