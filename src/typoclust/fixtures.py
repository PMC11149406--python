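"""Synthetic typology generator.

The study dataset this package was exercised on (four parent-attachment
scales for 793 adolescent boys) is available only on request, so the
generator produces a stand-in with the same qualitative anatomy: a planted
7-type centroid structure on four correlated scale variables, strongly
right-skewed anxiety-like distributions, and an optional Likert itemization
so the whole preprocessing path (truncation, scale construction,
reliability) can be exercised end to end.  All draws are seeded.

The default centroid pattern mirrors the sign structure of the published
7-cluster solution (two insecure types with very high anxiety and/or
avoidance, two large secure types, a "good mother - bad father" type, and
two types where avoidance and anxiety dissociate), with band-midpoint
z-values, cluster proportions close to the published cluster sizes, and a
within-cluster sd of 0.5 z-units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataMatrix, Partition
from .preprocess import LikertItemSet

__all__ = ["TypologySpec", "generate_typology", "DEFAULT_CENTROIDS", "skew_map"]

#: z-unit centroid pattern of the default 7-type structure
#: (variables: AvoidMo, AnxMo, AvoidFa, AnxFa)
DEFAULT_CENTROIDS = np.array(
    [
        [1.25, 0.00, 1.25, -0.375],   # avoidant, below-average anxiety
        [0.00, -0.375, 0.00, -0.375],  # mildly secure, large
        [-1.25, -0.375, -1.25, -0.375],  # strongly secure, large
        [0.00, 0.75, 0.00, 0.375],    # anxious, average avoidance
        [-0.375, -0.375, 1.25, 1.25],  # good mother - bad father
        [0.75, 2.75, 0.75, 2.25],     # extreme parental anxiety
        [1.25, 0.75, 0.75, 0.75],     # globally insecure
    ]
)

DEFAULT_PROPORTIONS = np.array([101, 211, 205, 80, 51, 71, 74]) / 793.0

DEFAULT_VAR_NAMES = ["AvoidMo", "AnxMo", "AvoidFa", "AnxFa"]

#: right-tail stretch factors emulating the skewness of anxiety scales
DEFAULT_SKEW = {"AnxMo": 1.8, "AnxFa": 1.8}


@dataclass
class TypologySpec:
    """Parameters of the synthetic typology.

    ``skew`` maps variable name -> right-tail stretch factor (> 1 stretches
    values above the variable's planted mean by that slope, producing the
    long right tail typical of anxiety scales).  ``items_per_scale`` turns
    each scale score into that many Likert items with rounding noise so the
    item-level pipeline can run.
    """

    n: int = 800
    proportions: np.ndarray = field(default_factory=lambda: DEFAULT_PROPORTIONS.copy())
    centroids: np.ndarray = field(default_factory=lambda: DEFAULT_CENTROIDS.copy())
    within_sd: float = 0.5
    var_names: list = field(default_factory=lambda: list(DEFAULT_VAR_NAMES))
    skew: dict = field(default_factory=lambda: dict(DEFAULT_SKEW))
    items_per_scale: int | None = None
    item_range: tuple = (1, 5)
    item_noise_sd: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        self.centroids = np.asarray(self.centroids, float)
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must sum to 1")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        if self.centroids.shape[0] != self.proportions.size:
            raise ValueError("centroid rows must match the number of proportions")
        if len(self.var_names) != self.centroids.shape[1]:
            raise ValueError("var_names length must match centroid columns")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def p(self) -> int:
        return self.centroids.shape[1]


def skew_map(x: np.ndarray, pivot: float, slope: float) -> np.ndarray:
    """Piecewise-linear monotone right-tail stretch.

    Identity below ``pivot``; values above it are stretched by ``slope``.
    slope > 1 yields positive skew while keeping the map strictly monotone.
    """
    return np.where(x <= pivot, x, pivot + slope * (x - pivot))


def generate_typology(spec: TypologySpec):
    """Draw a seeded synthetic sample with known true cluster labels.

    Returns ``(DataMatrix, Partition)`` — or ``(DataMatrix, Partition,
    LikertItemSet)`` when ``items_per_scale`` is set.  Labels are drawn from
    the cluster proportions, case values from per-cluster spherical
    Gaussians around the planted centroids, and each variable named in
    ``spec.skew`` is passed through the monotone right-tail stretch.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.k, size=spec.n, p=spec.proportions) + 1
    # guard against an empty cluster at small n
    for c in range(1, spec.k + 1):
        if not np.any(labels == c):
            labels[rng.integers(spec.n)] = c
    X = spec.centroids[labels - 1] + rng.normal(0, spec.within_sd, (spec.n, spec.p))
    for j, name in enumerate(spec.var_names):
        if name in spec.skew:
            pivot = float(spec.centroids[:, j].min())
            X[:, j] = skew_map(X[:, j], pivot, float(spec.skew[name]))
    data = DataMatrix(values=X, var_names=list(spec.var_names))
    part = Partition(labels, k=spec.k)
    if spec.items_per_scale is None:
        return data, part
    itemset = _itemize(X, spec, rng)
    return data, part, itemset


def _itemize(X: np.ndarray, spec: TypologySpec, rng: np.random.Generator) -> LikertItemSet:
    """Expand each scale score into Likert items: score + noise, rounded
    and clipped to the item range.  Scores are first mapped from z-units
    onto the raw item scale."""
    lo, hi = spec.item_range
    m = spec.items_per_scale
    n, p = X.shape
    mid = (lo + hi) / 2.0
    span = (hi - lo) / 6.0  # +-3 z-units cover the scale
    raw = mid + X * span
    items = np.empty((n, p * m))
    scale_map = {}
    for j in range(p):
        cols = list(range(j * m, (j + 1) * m))
        scale_map[spec.var_names[j]] = cols
        noise = rng.normal(0, spec.item_noise_sd, (n, m))
        block = np.clip(np.rint(raw[:, j : j + 1] + noise), lo, hi)
        items[:, cols] = block
    return LikertItemSet(
        items=items,
        lo=lo,
        hi=hi,
        scale_map=scale_map,
        max_missing={name: 0 for name in spec.var_names},
    )
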