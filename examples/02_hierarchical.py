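"""Hierarchical clustering: Ward agglomeration and DIANA division.

Clusters the default 7-type synthetic sample, prints the QC summary table
over k = 2..9 (the dendrogram-cut aid), and shows the pattern table of the
chosen 7-cluster solution.
"""

import typoclust as tc

data, truth = tc.generate_typology(tc.TypologySpec(seed=42))
z = tc.standardize(data)

dend = tc.ahca(z, method="ward", spec=tc.DistanceSpec("squared_euclidean"))
parts = [tc.cut_tree(dend, k) for k in range(2, 10)]
qc = tc.qc_table([tc.qc_set(z, p) for p in parts])
print("Ward AHCA quality coefficients by cluster number:")
print(qc[["EESS%", "XBmod", "HCmean", "HCmin", "HCmax"]].round(3).to_string())
print(
    "\nEESS% rises steeply until the planted k is reached and flattens "
    "after it; an acceptable solution needs EESS% > 70, XBmod > 0.50 and "
    "HCmean < 0.50.\n"
)

part7 = tc.cut_tree(dend, 7)
print("pattern of standardized means, 7-cluster Ward solution:")
print(tc.pattern_table(z, part7).to_frame().to_string())
print(
    "\nH/L flag above/below-average cluster means; extra '+' marks each "
    "additional half standard deviation.\n"
)

ddend = tc.diana(z, spec=tc.DistanceSpec("squared_euclidean"))
dqc = tc.qc_set(z, tc.cut_tree(ddend, 7))
print(
    f"DIANA divisive 7-cluster solution: EESS% = {dqc.EESS_pct:.1f}, "
    f"HCmean = {dqc.HCmean:.3f}"
)
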