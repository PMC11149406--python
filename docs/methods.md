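# Methods

This note documents the statistical machinery in `typoclust`, the design
choices that were genuinely open, and what the synthetic fixture can and
cannot establish about real data.

## Distances and standardization

All clustering operates on case distances.  Besides the six textbook
metrics (squared Euclidean, Euclidean, Manhattan, Canberra, maximum,
Minkowski with configurable power, default 2), the package uses the
**average squared Euclidean distance** ASED = ‖x − y‖²/p throughout its
quality and validation layer.  Standardization uses column z-scores with
the n−1 (sample) denominator; under that convention the mean ASED over all
unordered pairs of a standardized sample is exactly 2, which anchors the
homogeneity coefficient's noise baseline (HC of the whole standardized
sample = 2.0 identically) and makes the 0.7 nearest-neighbour outlier
threshold scale-free in p.  Missing values are never imputed inside the
distance layer; preprocessing must resolve them first.

## Preprocessing

- **Item truncation** fuses top response categories of heavily right-skewed
  Likert items (e.g. anxiety responses 4 and 5 set to 3) before scale
  construction.  Missing responses are untouched.
- **Scale scores** are means of the usable items, formed only when the
  number of missing items does not exceed the per-scale allowance
  (anxiety-type scales: none; avoidance-type scales: one), else missing.
- **Outlier screen**: a case is flagged when the mean ASED to its
  `neighbours` nearest other cases (default 1; exposed because residual
  screens sometimes average several neighbours) exceeds the threshold
  (default 0.7 on standardized variables).
- **Reliability** is computed per scale on listwise-complete cases (the
  usable-case counts therefore differ across scales).  Cronbach's alpha
  uses the standard m/(m−1)·(1 − Σvar_j/var_total) form with Feldt's exact
  F interval; McDonald's omega = (Σλ)²/((Σλ)² + Σθ) comes from a
  one-factor maximum-likelihood fit on the item correlation matrix
  (statsmodels), with a seeded percentile-bootstrap interval.  The exact
  interval constructions behind published reliability tables are rarely
  stated; Feldt + bootstrap are the standard defensible choices.  A
  non-convergent factor fit downgrades the scale to alpha-only with a
  warning record rather than failing the pipeline.

## Hierarchical clustering

Agglomeration is one generic **Lance–Williams** engine covering average,
single, complete, centroid, median, Ward, flexible-beta
(α_i = α_j = (1−β)/2, γ = 0, default β = −0.25, Milligan's recommendation)
and McQuitty linkage.  Ward follows the **ward.D convention**: the
recurrence is applied to the supplied distances, intended to be squared
Euclidean — under which each merge height equals twice the error-sum-of-
squares increment, so the heights sum to 2T (a tested identity).  Centroid
and median linkage likewise assume squared Euclidean input and may produce
height inversions; these are recorded on the dendrogram, not raised.
Tie-breaking is lexicographic on cluster slot indices (a merged cluster
occupies the smaller slot of its children), making trees deterministic and
permutation-equivariant.

Division implements **DIANA**: at each step the cluster with the largest
diameter is split by the splinter procedure — seed the object with maximal
average dissimilarity, then let objects defect one at a time (largest
positive gain first) while they are on average closer to the splinter group
than to the remainder.  Split height = parent diameter.  Because the
largest-diameter rule makes successive split heights non-increasing, the
split sequence reversed is a valid merge table, and one `cut_tree`
implementation (labels renumbered 1..k by first case appearance) serves
both directions: cutting a divisive tree at k reproduces the state after
k−1 splits.

## k-center methods

All three families start from k distinct cases sampled uniformly under the
run seed (k-means++ is available behind a flag but off by default) and keep
the best of `n_starts` runs by objective; labels are canonicalized by first
case appearance, so a fixed seed yields bit-identical partitions.

- **k-means** (objective: total WSS) in three classic flavours: Lloyd–Forgy
  batch; MacQueen online (running-mean center updates after every
  assignment); and Hartigan's first-variation transfer method — a point
  moves when the exact WSS change n_t/(n_t+1)·d(x,μ_t) − n_s/(n_s−1)·d(x,μ_s)
  is negative, cycling until no move.  The transfer method shares its fixed
  points with the full Hartigan–Wong algorithm; the live-set bookkeeping
  that accelerates large-n runs is omitted as unnecessary at this package's
  scale.  Empty clusters are re-seeded at the case farthest from the
  existing centers (recorded behaviour, not an error).
- **k-medoids** is PAM: greedy BUILD seeding then steepest-descent SWAP
  over all medoid/non-medoid exchanges; the objective sums distances (by
  default squared Euclidean, matching the rest of the package) to the
  cluster medoid, which is always an actual case.  BUILD is deterministic,
  so the default is a single start.
- **k-medians** alternates nearest-center assignment under the Euclidean
  metric with within-cluster **geometric medians** computed by Weiszfeld
  iteration (tol 1e-8, max 200 iterations) with the Vardi–Zhang
  subgradient correction when an iterate lands on a data point.  A batch
  alternating scheme was chosen over online/stochastic-gradient variants
  for exact reproducibility; in one dimension the center reduces to the
  coordinate median.

## Model-based clustering

Gaussian mixtures under the 14 eigen-decomposition covariance families
Σ_c = λ_c D_c A_c D_cᵀ (volume / shape / orientation, each Equal, Variable
or Identity).  The M-steps use the Celeux–Govaert closed forms; VEI, VEE
and VEV use short inner flip-flop iterations between volumes and the shared
shape; the shared-orientation families EVE/VVE update D by a
majorize–minimise step over the orthogonal group (each step a Procrustes
solve; inner tol 1e-8, max 100).  Free-parameter counts are
m = (k−1) + kp + m_cov with m_cov assembled from {volume: 1 or k} +
{shape: 0, p−1 or k(p−1)} + {orientation: 0, p(p−1)/2 or k·p(p−1)/2}.

BIC uses the "larger is better" convention 2ℓ − m·log n; ICL subtracts
twice the classification entropy, so ICL ≤ BIC with equality exactly for
0/1 posteriors.  The grid (default k = 2–9, allowed 2–25, all 14 families)
is fitted from a deterministic initialization: a Ward-linkage hard
partition at each k (scipy's linkage, used only for seeding).  Covariance
collapse — any component covariance with minimum eigenvalue below 1e-10 ×
the mean variable variance, or a vanishing soft count — marks the cell
non-converged and excludes it from selection; nothing raises, mirroring the
gaps practitioners see in BIC plots.  Classification is MAP with
uncertainty u_i = 1 − max_c z_ic; ties break to the lowest cluster index.

## Quality coefficients

HC_c = 2·WSS_c/(p·(n_c−1)) (singletons: 0); HCmean is size-weighted.  The
identity Σ_c (n_c−1)·HC_c·p/2 = TotalWSS links HC to EESS% =
100·(T − TotalWSS)/T and yields the practically useful approximation
EESS% ≈ 100·(1 − HCmean/2) when all clusters are reasonably large.

**XBmod is a reconstruction.**  The published formula for the modified
Xie–Beni index lives in a source we could not obtain; the implementation
uses min inter-centroid ASED − HCmean because it (a) is a separation
measure on the same ASED scale, (b) goes negative exactly for overlapping
solutions, and (c) produces magnitudes consistent with published summary
tables.  It is isolated in a single function (`quality.xbmod`) for easy
replacement if the original definition becomes available.

Homogeneity percentages use strict inequality (HC < T); note that
recomputing them from *rounded* printed HC values is unstable exactly at
the thresholds (a printed HC of 0.20 contributes nothing to Hom20 even if
the unrounded value was 0.195).  Pattern codes band the standardized
cluster means: |z| < 0.25 → "."; [0.25, 0.5) → (H)/(L); [0.5, 1.0) → H/L;
each further 0.5 adds one "+", capped at "++++" for |z| ≥ 2.5.  The bands
are configurable; the defaults make published pattern tables qualitatively
consistent.

## MORI validation

Null replicates are multivariate normal with the observed intercorrelations,
generated as x = A·z from the varimax-rotated full PCA loading matrix
(A·Aᵀ = R exactly, since all components are retained and the rotation is
orthogonal — Kaiser row-normalization is a no-op at unit communalities).
Each replicate is re-standardized and clustered with the *same*
configuration as the observed solution, with a fresh seed spawned from the
master seed, so runs are independent yet bit-reproducible.  The default is
25 replicates.

**The MORI formulas are reconstructions** around "relative improvement over
random-data clustering" with per-QC ideal values: EESS% → (obs − r̄)/(100 − r̄);
mean silhouette → (obs − r̄)/(1 − r̄); HCmean (smaller is better, ideal 0) →
(r̄ − obs)/r̄; XBmod → (obs − r̄)/(2 − r̄), the reference 2 being the expected
ASED of independent standardized cases.  A null mean sitting exactly at the
ideal value leaves that QC's MORI undefined (reported as such).  The
formulas live in one function (`validation._mori_one`).  Calibration: data
drawn from the null generator itself produce MORI within ±0.1 of zero at 25
replicates (a tested property), and the default moderately-separated
7-type fixture yields MORI around 0.3–0.4 — a medium-sized dominance.

Cross-solution agreement uses optimal assignment (minimum total ASED
between centroid sets; maximum total CMR between partitions).  Published
analyses imply but do not state how corresponding pairs are chosen; optimal
assignment is the defensible canonical choice and is symmetric.

## The synthetic typology generator

The generator emulates the anatomy of a four-scale parent-attachment
dataset that is available only on request: k = 7 planted types with a
centroid sign pattern mirroring the published 7-cluster solution
(band-midpoint z-values), cluster proportions proportional to the published
sizes, within-type isotropic Gaussian noise of sd 0.5 z-units, n = 800, and
a monotone piecewise-linear right-tail stretch (slope 1.8 above the lowest
planted centroid) applied to the two anxiety-like variables, producing
skewness in the 1.0–2.2 range typical of anxiety scales.  Optional
itemization expands each scale score into Likert items (score + rounding
noise, clipped to the 1–5 range) so truncation, scale building and
reliability can be exercised end to end.

What the fixture does **not** emulate: non-Gaussian within-type shapes
beyond the marginal skewing, floor effects from discrete item averaging,
missing-data mechanisms, and whatever sampling structure the real cohort
had.  Tests passing on the fixture therefore establish the *algorithms*
(recovery of a known structure under realistic separation and skew), not
any substantive claim about real attachment data.

## Problem sizes and numerical conventions

Tests and the acceptance script run the pipeline at the study's natural
scale (n = 800, p = 4, k = 7), mixture recovery at n = 900–3000, and all
brute-force oracles at n ≤ 20, sizes at which exhaustive enumeration is
exact.  EM tolerance 1e-6 on the relative log-likelihood (max 500
iterations); Weiszfeld and inner M-step loops 1e-8; k-center tolerance
1e-8 on the objective.  Degenerate inputs are rejected early with named
offenders (constant columns, rank-deficient correlation matrices, empty
clusters, out-of-range k).

## Known limitations

- XBmod and the MORI denominators are reconstructions (see above); absolute
  values should be compared across solutions computed by this package, not
  against other software, until the original definitions are reconciled.
- The Hartigan–Wong implementation is the first-variation transfer method
  without live-set acceleration; results agree at convergence but iteration
  counts differ from the classic Fortran implementation.
- PAM is exact steepest-descent SWAP (O(k·n²) per scan); no CLARA-style
  subsampling, so very large samples (n ≫ 10⁴) will be slow.
- The one-factor omega model assumes congeneric items; multi-factor or
  hierarchical omega is out of scope.
- Mixture fits use a hard variance floor rather than Bayesian
  regularization; heavily overlapping components at small n may be marked
  non-converged where a prior-based EM would return a fit.
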