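"""Shared domain types and distance computations.

The central container is :class:`DataMatrix`, a cases-by-variables matrix of
quantitative scores (typically Likert-derived scale means) with explicit
missing-value bookkeeping and a standardization flag.  All clustering and
validation stages consume it.

Distances follow the conventions of classical person-oriented cluster
analysis: six textbook metrics plus ASED, the *average squared Euclidean
distance* — squared Euclidean distance divided by the number of variables.
For independent standardized variables the expected ASED of two random cases
is 2, which makes ASED-based thresholds (outlier screening at 0.7,
per-cluster homogeneity coefficients) scale-free in the number of variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DataMatrix",
    "DistanceSpec",
    "Partition",
    "ClusterSolution",
    "pairwise_distances",
    "standardize",
]

_DISTANCE_NAMES = (
    "squared_euclidean",
    "euclidean",
    "manhattan",
    "canberra",
    "maximum",
    "minkowski",
    "ased",
)


@dataclass(frozen=True)
class DistanceSpec:
    """A case-distance choice.

    ``ased`` is squared Euclidean distance divided by the number of
    variables p; ``minkowski`` takes a power (default 2, which reduces to
    Euclidean, mirroring the common ``dist`` convention).
    """

    name: str = "squared_euclidean"
    minkowski_power: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in _DISTANCE_NAMES:
            raise ValueError(
                f"unknown distance {self.name!r}; choose from {_DISTANCE_NAMES}"
            )
        if self.minkowski_power <= 0:
            raise ValueError("minkowski_power must be > 0")


@dataclass
class DataMatrix:
    """Rectangular case x variable matrix of real scores.

    Missing values are stored as NaN in ``values``; ``missing_mask`` is the
    derived boolean view.  When ``standardized`` is set, every complete
    column has sample mean 0 and sample sd 1 (n-1 denominator) and the
    original per-variable ``(mean, sd)`` pairs are retained so cluster
    centroids can be expressed on the raw scale again.
    """

    values: np.ndarray
    case_ids: list = None
    var_names: list = None
    standardized: bool = False
    standardization_params: np.ndarray | None = None  # (p, 2): mean, sd

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 cases and 1 variable")
        if self.case_ids is None:
            self.case_ids = list(range(1, n + 1))
        if self.var_names is None:
            self.var_names = [f"v{j + 1}" for j in range(p)]
        if len(self.case_ids) != n or len(self.var_names) != p:
            raise ValueError("id/name lengths do not match the matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DataMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            case_ids=list(df.index),
            var_names=[str(c) for c in df.columns],
            **kw,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.case_ids, columns=self.var_names)

    def select(self, var_names: Sequence[str]) -> "DataMatrix":
        """Column-subset by variable name, preserving standardization state."""
        idx = [self.var_names.index(v) for v in var_names]
        params = (
            self.standardization_params[idx]
            if self.standardization_params is not None
            else None
        )
        return DataMatrix(
            values=self.values[:, idx],
            case_ids=list(self.case_ids),
            var_names=[self.var_names[i] for i in idx],
            standardized=self.standardized,
            standardization_params=params,
        )


@dataclass
class Partition:
    """Hard cluster membership: integer labels 1..k covering every case."""

    labels: np.ndarray
    k: int = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k is None:
            self.k = int(self.labels.max())
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k or len(present) != self.k:
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty cluster; got {present}"
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def relabel_by_first_appearance(self) -> "Partition":
        """Canonical labelling: cluster 1 is the cluster of the first case, etc."""
        mapping = {}
        new = np.empty_like(self.labels)
        nxt = 1
        for i, lab in enumerate(self.labels):
            if lab not in mapping:
                mapping[lab] = nxt
                nxt += 1
            new[i] = mapping[lab]
        return Partition(new, self.k)


@dataclass
class ClusterSolution:
    """A partition together with its centers and the optimised objective."""

    partition: Partition
    centroids: np.ndarray
    objective: float
    method_meta: dict = field(default_factory=dict)
    hc_per_cluster: np.ndarray | None = None
    medoid_indices: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.partition.k


def _require_complete(data: DataMatrix) -> np.ndarray:
    if data.has_missing():
        raise ValueError(
            "data contain missing values; run preprocessing "
            "(build_scales / complete_cases) before computing distances"
        )
    return data.values


def pairwise_distances(data: DataMatrix | np.ndarray, spec: DistanceSpec) -> np.ndarray:
    """Symmetric n x n matrix of case distances under ``spec``.

    ASED entries equal the squared-Euclidean entries divided by p exactly.
    """
    if isinstance(data, DataMatrix):
        X = _require_complete(data)
    else:
        X = np.asarray(data, dtype=float)
        if np.isnan(X).any():
            raise ValueError("data contain missing values")
    p = X.shape[1]
    name = spec.name
    if name == "squared_euclidean":
        d = pdist(X, "sqeuclidean")
    elif name == "ased":
        d = pdist(X, "sqeuclidean") / p
    elif name == "euclidean":
        d = pdist(X, "euclidean")
    elif name == "manhattan":
        d = pdist(X, "cityblock")
    elif name == "canberra":
        d = pdist(X, "canberra")
    elif name == "maximum":
        d = pdist(X, "chebyshev")
    elif name == "minkowski":
        d = pdist(X, "minkowski", p=spec.minkowski_power)
    else:  # pragma: no cover - guarded by DistanceSpec
        raise ValueError(name)
    return squareform(d)


def standardize(data: DataMatrix) -> DataMatrix:
    """Column z-scores with the n-1 (sample) sd denominator.

    Missing entries stay missing; moments are computed on the non-missing
    part of each column.  Idempotent: standardizing twice equals once.
    Raises on constant columns, naming the offender.
    """
    X = data.values.copy()
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=1)
    bad = np.where(~(sds > 0))[0]
    if bad.size:
        names = [data.var_names[j] for j in bad]
        raise ValueError(f"cannot standardize constant column(s): {names}")
    Z = (X - means) / sds
    if data.standardized and data.standardization_params is not None:
        params = data.standardization_params
    else:
        params = np.column_stack([means, sds])
    return replace(
        DataMatrix(
            values=Z,
            case_ids=list(data.case_ids),
            var_names=list(data.var_names),
        ),
        standardized=True,
        standardization_params=params,
    )
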