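"""Model-based clustering: the 14 Gaussian-mixture covariance families.

Searches the model grid on the default synthetic typology, prints the BIC
table, the winning model, and the classification uncertainty.
"""

import numpy as np

import typoclust as tc

data, truth = tc.generate_typology(tc.TypologySpec(seed=42))
z = tc.standardize(data)

grid = tc.model_search(z, k_range=range(2, 10))
print("BIC table (rows = k, columns = covariance family; blank = no fit):")
print(grid.bic.round(0).to_string())

best = grid.best("bic")
part, uncertainty = tc.classify(best)
qc = tc.qc_set(z, part)
print(
    f"\nbest model by BIC: {best.model_name} with k = {best.k} "
    f"(BIC = {best.bic:.1f}, ICL = {best.icl:.1f})"
)
print(
    f"classification: EESS% = {qc.EESS_pct:.1f}, HCmean = {qc.HCmean:.3f}, "
    f"mean uncertainty = {uncertainty.mean():.4f}"
)
print(
    "\nThe spherical-family winner mirrors how the sample was built "
    "(isotropic within-cluster noise); uncertainty near 0 means the "
    "components barely overlap.  ICL equals BIC exactly when every case "
    "is assigned with certainty."
)
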