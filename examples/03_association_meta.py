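"""Two synthetic cohorts end to end: models, meta-analysis, FDR.

Fits standardized trait ~ metformin + full covariate set per cohort, pools
the two cohorts per trait with DerSimonian-Laird, and controls the FDR
across the 45 traits with Benjamini-Hochberg at Q = 0.05.  A planted
negative metformin effect on fucosylated diantennary analytes should
surface in the fucosylation traits.
"""

import pandas as pd

from glycomeds.meta import run_meta_pass
from glycomeds.simulate import PlantedEffect, diagene_like, hoorn_like
from glycomeds.studies import cohort_association_pass

effect = [PlantedEffect("metformin", {"antennarity": 2, "fucosylated": True}, -0.15)]
cfg_a = diagene_like(seed=1, n_subjects=1200, planted_effects=effect)
cfg_b = hoorn_like(seed=2, n_subjects=1000, planted_effects=effect)

res = pd.concat(
    [
        cohort_association_pass(cfg_a, "metformin", "full"),
        cohort_association_pass(cfg_b, "metformin", "full"),
    ],
    ignore_index=True,
)
pooled = run_meta_pass(res, q_cut=0.05)

sig = pooled[pooled["significant"]].sort_values("p_value")
print(f"{int(pooled['significant'].sum())} of {len(pooled)} traits significant at Q<=0.05\n")
print("top pooled associations (beta in SD units):")
cols = ["trait", "pooled_beta", "pooled_se", "q_value", "i2"]
print(sig[cols].head(8).to_string(index=False, float_format=lambda v: f"{v: .4f}"))
print(
    "\nNegative betas on A2F-family traits reflect the planted decrease in\n"
    "fucosylated diantennary abundance among metformin users; I2 near 0\n"
    "means the two cohorts agree (little heterogeneity)."
)
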