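# Methods

## Structural annotation from composition

A direct analyte is a monosaccharide composition `H<h>N<n>[F<f>][E<e>][L<l>]`
(hexoses, N-acetylhexosamines, fucoses, α2,6- and α2,3-linked sialic acids;
the E/L split is measurable after linkage-specific derivatization, which
ethyl-esterifies α2,6- and lactonizes α2,3-linked sialic acids). Composition
alone does not fix a structure, so annotation is a rule set encoding
standard total-plasma-glycome conventions:

* N = 2: high-mannose if H ≥ 4, otherwise "other".
* N = 3: hybrid if H ≥ 6, else complex monoantennary (A1).
* N ≥ 4: complex, with raw antennarity a = N − 2 and galactoses G = H − 3.
* Bisection: plasma tri-/tetra-antennary glycans are near-fully
  galactosylated, so an extra HexNAc on an under-galactosylated backbone is
  read as a bisecting GlcNAc on an IgG-type structure: a = 3 is a bisected
  diantennary iff H ≤ 5 (else A3); a = 4 a bisected triantennary iff H ≤ 6
  (else A4); a = 5 a bisected tetra-antennary.

Any label can be re-annotated through a TSV override table when orthogonal
evidence exists. Inconsistent compositions (sialic acids exceeding
galactoses, galactoses exceeding antennae) are flagged `valid=False` and
silently excluded from all trait numerators and denominators — one bad
analyte must not abort a cohort run. Fucose counts > 1 are treated as
fucosylated without distinguishing core from antennary fucose.

## Derived-trait calculus

The 45 derived traits live in `src/glycomeds/data/trait_registry.yaml` as
data, not code: each entry is a numerator selector, a denominator selector
and a weight. Unit weights give "X within Y" fractions; `G/antenna` etc.
give per-antenna feature averages (dividing each glycan's count by its
antennarity); `S/galactose` etc. give per-galactose averages, with
agalactosylated species excluded from both sums. Sialylated (S) means
E + L ≥ 1; E0/L0/S0 name fragments mean the respective count is exactly
zero regardless of the other linkage. Antennarity selectors include
bisected species of the same antennarity. MHy (high-mannose : hybrid) is a
ratio trait, exempt from the numerator-⊆-denominator and [0,1] expectations.
A zero or empty denominator yields a missing value, never 0. Known naming
ambiguities in the circulating trait descriptions (A3S, A4S, A2F0GL) are
resolved in favour of the trait *name* and flagged in the registry header
rather than silently rewritten.

Consequences that double as test invariants: CA1+CA2+CA3+CA4 = 1 wherever
complex glycans are present; all unit/per-antenna/per-galactose traits lie
in [0, 1] for valid annotations; traits are invariant to rescaling a
subject's raw row.

## Preprocessing

Stages are explicit and monotone: raw → qc_passed → normalized →
batch_corrected → standardized; out-of-order calls raise. QC drops analytes
with median relative intensity < 1e-4 or detection rate < 0.5 (defaults,
both exposed), plus an explicit exclusion list for known interferences, and
subjects with zero total signal — every exclusion is reported with its
reason. Total-area normalization divides each row by its sum.

Batch correction is per-analyte log-scale median centering within batch,
re-centered to the global median. Because renormalizing rows to the simplex
perturbs the aligned medians, the center-and-renormalize step is iterated
to a fixed point; clean multiplicative batch structure converges below
1e-13, while heterogeneous noisy data reaches an irreducible floor (row-sum
coupling) detected by a no-progress stop — in practice the planted shift is
reduced by ≥ 95% and a post-hoc batch regression term is null. Zeros are
replaced by half the analyte's smallest positive value before the log.
Median centering was chosen over ComBat-style pooling for robustness,
compositional safety and light dependencies; the method is pluggable.

Standardization uses the sample SD (n − 1) and is always per cohort, never
pooled. A zero-variance column is an error naming the column.

## Association models

The outcome is a standardized trait, so betas are SD-unit differences
between users and non-users at fixed covariates. Sex is coded female = 0;
age is mean-centered within cohort before the age×sex product is formed
(this only reparameterizes the intercept/main effects — the medication beta
is invariant). Smoking enters as two dummies (former, current; never =
reference). Missing data are handled by complete-case analysis per model,
with per-term missing counts reported so model-specific n is visible.
P-values are two-sided t (OLS) and Wald (logistic, Newton/IRLS, deviance
tolerance 1e-10, max 100 iterations); perfect separation is flagged on the
result, not raised. A vectorized multi-outcome OLS (`fit_linear_many`)
shares one design factorization across the 45 traits; its numerical
equivalence to the per-trait path is a unit test, and it is what the
pipeline and the replicate studies use.

## Meta-analysis and FDR

DerSimonian–Laird with fixed-effect weights w = 1/se²:
Q = Σw(β−β_FE)², C = Σw − Σw²/Σw, τ² = max(0, (Q−(k−1))/C), random-effects
weights 1/(se²+τ²), normal inference on the pooled effect (classical DL;
no Knapp–Hartung, and no REML/Paule–Mandel since k = 2 makes refinements
moot). I² = max(0, (Q−(k−1))/Q). Benjamini–Hochberg is applied within the
per-medication, per-model family of traits by default (a `global` scope is
a switch, recorded in output headers), with significance at Q ≤ 0.05.

## Synthetic cohorts and ground truth

The generator emulates two diabetes cohorts. Covariates follow normal
(age, BMI, HbA1c, blood-pressure components), gamma (duration,
triglycerides) and categorical families with preset parameters mirroring
the published cohort tables (e.g. age 65.21 ± 10.58 vs 64.48 ± 10.63;
metformin 51.1% vs 68.3%; 70 vs 68 analytes). ACR histories are drawn and
nephropathy is derived through the clinical rule, eGFR through the MDRD
equation. Medication assignment is logistic on standardized covariates
(HbA1c/BMI/duration for glucose-lowering drugs; MAP/CVD/nephropathy for
ACE-i/ARB; CVD/non-HDL/age for statins), with the intercept bisection-
calibrated to the target prevalence — confounding by indication whose
drivers are all inside the corresponding full model, so correct adjustment
is possible in principle.

Log-abundances are baseline + covariate loadings + latent family factors +
planted effects + batch shifts + N(0, 0.4) noise + a per-subject scale,
then exponentiated; raw intensities are *not* normalized (the pipeline must
do that). Baselines are a pure function of the panel (digest-seeded
jitter), so a panel's generative profile does not depend on the run seed.
Block correlation comes from three latent factors (fucosylation,
sialylation, branching capacity) — a labelled assumption, as real
between-analyte correlation is not published. Planted effects are log-scale
shifts on the analytes matching a structural selector; a −0.25 shift on
fucosylated diantennary species is the reference condition.

Because total-area normalization couples analytes, the induced effect on
any derived trait is defined by a Monte-Carlo counterfactual oracle: draw a
large cohort, evaluate each subject's trait with the medication forced on
and off under identical noise, and divide the mean paired difference by the
factual trait SD. The oracle is evaluated on batch-free data since the
pipeline standardizes after batch correction. Fully disjoint ratio traits
(e.g. MHy) are provably untouched (the renormalization factor cancels);
total-denominator traits move visibly through coupling — truth is the
oracle, not the planted number.

What the generator does not emulate: raw spectra and peak interference,
non-MCAR missingness, dose/duration effects, real covariate-glycan effect
sizes (loadings are plausible, small, and limited to age/sex), and real
between-analyte correlation. Passing recovery/FDR tests therefore shows the
*inference machinery* is sound under the stated generative model, not that
the biological effect sizes are realistic.

## Study sizes and numerical choices

The recovery study uses 2,000 subjects per cohort with a 200,000-subject
oracle; the type-I-error study uses 500 replicate two-cohort passes at 250
subjects per cohort via the vectorized OLS path — sizes chosen so the full
verification runs in minutes on one CPU while keeping the Monte-Carlo error
of each check well below its tolerance. Tolerances: exact algebraic
identities at 1e-12, fitted coefficients vs oracles at 1e-8, recovery
within ±0.06 of the oracle, empirical FDR ≤ 0.06 at a nominal 0.05. Seeds
are explicit everywhere; (config, seed) reproduces outputs bit-identically.

## Known limitations

Bisection inference from composition alone is heuristic (hence the override
table). The batch method assumes batches share a common biological median
profile. The logistic model reports Wald intervals only. Cross-sectional
associations carry no causal claim — the subgroup/co-medication variants
probe robustness, not causality.
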