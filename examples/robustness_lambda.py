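"""Setup-uncertainty robustness: 30 perturbation scenarios and lambda.

Compares a functional-sparing dose (steep gradients around the hippocampus)
with a standard dose (flat inside the target) under the canonical 30 rigid
setup-error scenarios. The lambda index is the best-minus-worst spread of a
DVH metric across a magnitude group, normalized to the nominal value; steep
avoidance gradients make the spared structures far more sensitive.
"""

import numpy as np

from csieval import (DoseMetricSpec, PhantomSpec, fp_recipe, generate_dose,
                     generate_phantom, robustness_study, s_recipe)

spec = PhantomSpec(grid_shape=(50, 50, 125), spacing_mm=(4.0, 4.0, 4.0), seed=2)
template, masks = generate_phantom(spec)
rng = np.random.default_rng(2)
dose_fp = generate_dose(template, masks, fp_recipe(), rng)
dose_s = generate_dose(template, masks, s_recipe(), rng)

metrics = {"hippocampus": DoseMetricSpec("D_percent", 40.0),
           "PTV_cranial": DoseMetricSpec("D_percent", 95.0)}

for arm, dose in (("functional-sparing", dose_fp), ("standard", dose_s)):
    _, summary = robustness_study(dose, masks, metrics)
    hip = summary[summary["structure"] == "hippocampus"]
    lams = "  ".join(f"{r.group}: {r.lambda_percent:5.1f}%"
                     for r in hip.itertuples())
    print(f"{arm:>20} hippocampal lambda(D40%):  {lams}")

print("\nLarger lambda = larger metric swing across setup errors = less robust.")
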