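"""Simulate a cohort and run QC, normalization and batch correction.

Raw MS intensities carry no absolute scale; dividing each subject's row by
its sum makes the data compositional.  Batch correction aligns per-batch
log-scale medians per analyte while keeping rows on the simplex.
"""

import numpy as np

from glycomeds import batch_correct, normalize_total_area, qc_filter, simulate_cohort
from glycomeds.simulate import hoorn_like

cfg = hoorn_like(seed=11, n_subjects=400, n_batches=3, batch_sd=0.3)
cohort = simulate_cohort(cfg)
print(f"simulated {len(cohort.clinical)} subjects x {cohort.abundances.values.shape[1]} analytes")

m, report = qc_filter(cohort.abundances)
print(f"QC: {len(report.excluded_analytes)} analytes and "
      f"{len(report.excluded_subjects)} subjects excluded")

m = normalize_total_area(m)
print(f"row sums after normalization: max deviation from 1 = "
      f"{np.abs(m.values.sum(axis=1) - 1).max():.2e}")

batches = m.batch.unique()
gap = lambda v: np.abs(
    np.log(v[m.batch == batches[0]].median()) - np.log(v[m.batch == batches[1]].median())
).max()
print(f"largest between-batch median log-gap before correction: {gap(m.values):.3f}")
m = batch_correct(m)
print(f"                                 ... after correction: {gap(m.values):.2e}")
print(f"rows still sum to 1: max deviation = "
      f"{np.abs(m.values.sum(axis=1) - 1).max():.2e}")
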