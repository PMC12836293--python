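"""Run the whole evaluation pipeline on a synthetic two-patient cohort.

Produces the five report tables (dosimetry, NTCP, robustness, complexity,
delta-DVH) plus a provenance manifest, then prints the NTCP comparison —
the headline result: functional sparing cuts the predicted neurocognitive
and endocrine risks while the other models barely move.
"""

import pandas as pd

from csieval import EvaluationConfig, run_pipeline

cfg = EvaluationConfig(n_patients=2, seed=7,
                       grid_shape=(40, 40, 100), spacing_mm=(5.0, 5.0, 5.0),
                       output_dir="pipeline_demo")
paths = run_pipeline(cfg)
print("written:", ", ".join(f"{k}={v}" for k, v in paths.items()), "\n")

ntcp = pd.read_csv(paths["ntcp"])
cols = ["metric", "FP_mean", "FP_sd", "S_mean", "S_sd", "t_p"]
print(ntcp[cols].to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
print("\nFP = functional-sparing arm, S = standard arm; paired t-test p-values.")
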