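"""Item-level preprocessing: truncation, scale building, outlier screening,
reliability.

Generates an itemized synthetic attachment-style sample (four scales, each
measured by four 5-point Likert items), fuses the top anxiety categories to
tame the right skew, builds scale scores under the missing-item allowance,
screens for multivariate outliers, and reports alpha/omega reliability.
"""

import numpy as np

import typoclust as tc

spec = tc.TypologySpec(n=600, seed=42, items_per_scale=4)
data, truth, items = tc.generate_typology(spec)

# fuse anxiety responses of 4 and 5 into 3 (right-skew remedy)
capped = tc.truncate_items(items, {"AnxMo": 3, "AnxFa": 3})
scales = tc.build_scales(capped)
scales = tc.complete_cases(scales)
print(f"built {scales.p} scales for {scales.n} complete cases")

z = tc.standardize(scales)
screen = tc.nn_outliers(z, threshold=0.7)
print(f"outlier screen (nearest-neighbour ASED > 0.7): {screen.n_flagged} flagged")

rel = tc.reliability(capped, n_boot=200, seed=1)
print("\nreliability (Cronbach alpha / McDonald omega, 95% CIs):")
print(rel.to_dataframe().round(3).to_string())
print(
    "\nAvoidance scales reach alpha near 0.8; the heavily right-skewed "
    "anxiety items are noisier, which is exactly why their top categories "
    "get fused before scale construction.  The outlier count shows whether "
    "any case is isolated from all its neighbours in z-space."
)
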