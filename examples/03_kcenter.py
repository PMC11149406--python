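"""k-center partitioning: k-means, PAM k-medoids and k-medians at k = 7.

Compares the three families on the default synthetic typology and reports
homogeneity percentages — the share of cases living in very homogeneous
clusters (HC below 0.10/0.20/0.30/0.50).
"""

import numpy as np

import typoclust as tc

data, truth = tc.generate_typology(tc.TypologySpec(seed=42))
z = tc.standardize(data)
D = tc.pairwise_distances(z, tc.DistanceSpec("ased"))

solutions = {
    "k-means": tc.kmeans(z, tc.KCenterConfig(k=7, algorithm="hartigan_wong",
                                             seed=1, n_starts=10)),
    "k-medoids": tc.kmedoids(z, tc.KCenterConfig(k=7, algorithm="pam")),
    "k-medians": tc.kmedians(z, tc.KCenterConfig(k=7, algorithm="kmedians",
                                                 seed=1, n_starts=10)),
}

rows = []
for name, sol in solutions.items():
    qc = tc.qc_set(z, sol.partition, D=D)
    ct = tc.exacon_cmr(truth, sol.partition)
    rows.append(
        (name, qc.EESS_pct, qc.HCmean, qc.Hom20, qc.Hom50,
         np.mean([c for *_, c in ct.pairs]))
    )

print(f"{'method':<10} {'EESS%':>6} {'HCmean':>7} {'Hom20%':>7} "
      f"{'Hom50%':>7} {'CMR vs truth':>13}")
for name, eess, hcm, h20, h50, cmr in rows:
    print(f"{name:<10} {eess:>6.1f} {hcm:>7.3f} {h20:>7.1f} {h50:>7.1f} {cmr:>13.2f}")
print(
    "\nAll three families recover the planted 7-type structure (CMR vs "
    "truth near 1); the homogeneity percentages show how much of the "
    "sample sits in tight, interpretable types."
)
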