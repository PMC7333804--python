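"""Parse glycan compositions, annotate their structure, compute derived traits.

A composition string like "H5N4F1E2" counts hexoses (H), N-acetylhexosamines
(N), fucoses (F) and sialic acids by linkage (E: alpha2,6; L: alpha2,3).
Structural annotation turns counts into class / antennarity / bisection /
galactosylation features, and derived traits summarise structural families
as weighted ratios.
"""

import pandas as pd

from glycomeds import annotate, parse_composition
from glycomeds.glycan import annotate_panel
from glycomeds.traits import compute_trait_matrix, load_registry

for label in ("H5N2", "H5N4F1E2", "H5N5F1", "H6N5E2", "H7N6F1E2L1"):
    a = annotate(parse_composition(label))
    print(
        f"{label:>12}  class={a.glycan_class:<12} antennae={a.antennarity} "
        f"bisected={a.bisected} galactoses={a.galactoses} sialic={a.sialic_total}"
    )

# a toy 6-analyte panel for one subject, abundances summing to 1
panel = ["H5N4", "H5N4F1", "H5N4F1E2", "H5N5F1", "H6N5E1", "H5N2"]
row = pd.Series([0.15, 0.20, 0.30, 0.05, 0.20, 0.10], index=panel)
anns = annotate_panel(panel)
registry = load_registry()
tm = compute_trait_matrix(pd.DataFrame([row]), anns, registry)

print("\nSelected derived traits for the toy subject:")
for name in ("CA2", "CA3", "A2F", "A2E", "A2FS0B", "TA2FS0"):
    print(f"  {name:>8} = {tm[name].iloc[0]:.4f}")
print(
    "\nA2F is the fucosylated fraction of diantennary glycans; A2E the mean\n"
    "number of alpha2,6-sialic acids per antenna in them; TA2FS0 the share\n"
    "of fucosylated non-sialylated diantennary species in the whole profile."
)
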