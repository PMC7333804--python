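"""End-to-end simulation studies: effect recovery and type-I-error control.

These drive the whole chain in memory — simulate two cohorts, preprocess,
compute derived traits, standardize per cohort, fit the medication model,
pool with DerSimonian-Laird and apply BH — and measure how well the pipeline
recovers planted effects (or stays quiet when there are none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glycan import annotate_panel
from .meta import run_meta_pass
from .models import build_model_spec, fit_linear_many
from .preprocess import batch_correct, normalize_total_area, qc_filter, standardize
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    diagene_like,
    hoorn_like,
    oracle_trait_effect,
    simulate_cohort,
)
from .traits import compute_trait_matrix, load_registry

__all__ = [
    "FUCOSYLATED_A2",
    "metformin_recovery_configs",
    "cohort_association_pass",
    "recovery_study",
    "fdr_study",
    "RecoveryResult",
]

# target analyte family for the reference planted effect
FUCOSYLATED_A2 = {"antennarity": 2, "fucosylated": True}


def metformin_recovery_configs(
    seed: int, n_per_cohort: int = 2000, log_shift: float = -0.25
) -> tuple[SimulationConfig, SimulationConfig]:
    """Two-cohort preset pair with a planted metformin effect lowering
    fucosylated diantennary analytes."""
    effect = [PlantedEffect("metformin", FUCOSYLATED_A2, log_shift)]
    cfg_a = diagene_like(seed=seed, n_subjects=n_per_cohort, planted_effects=effect)
    cfg_b = hoorn_like(seed=seed + 1, n_subjects=n_per_cohort, planted_effects=effect)
    return cfg_a, cfg_b


def cohort_association_pass(
    config: SimulationConfig,
    medication: str,
    variant: str = "full",
    registry=None,
) -> pd.DataFrame:
    """Simulate one cohort and run it through preprocessing, traits,
    standardization and the association model; tidy per-trait results."""
    if registry is None:
        registry = load_registry()
    cohort = simulate_cohort(config)
    m, _ = qc_filter(cohort.abundances)
    m = normalize_total_area(m)
    m = batch_correct(m)
    anns = annotate_panel(m.values.columns)
    tm = compute_trait_matrix(m.values, anns, registry)
    tm = standardize(tm)
    spec = build_model_spec(medication, variant)
    results = fit_linear_many(tm, cohort.clinical, spec, cohort=config.name)
    return pd.DataFrame([r.as_dict() for r in results]).rename(
        columns={"model": "model"}
    )


@dataclass
class RecoveryResult:
    trait: str
    pooled_beta: float
    pooled_se: float
    oracle_effect: float
    per_cohort_oracle: dict[str, float]


def recovery_study(
    seed: int = 0,
    n_per_cohort: int = 2000,
    trait: str = "A2F",
    log_shift: float = -0.25,
    oracle_n: int = 200_000,
    variant: str = "full",
) -> RecoveryResult:
    """Planted-effect recovery: pooled full-model beta vs the Monte-Carlo
    counterfactual oracle for one trait.

    The oracle is evaluated once per cohort preset (the two cohorts differ
    in panel and covariate mix) and averaged with the same inverse-variance
    logic the meta-analysis would apply to identical-n cohorts — i.e. the
    plain mean, since both cohorts are simulated at the same size.
    """
    cfg_a, cfg_b = metformin_recovery_configs(seed, n_per_cohort, log_shift)
    res = pd.concat(
        [
            cohort_association_pass(cfg_a, "metformin", variant),
            cohort_association_pass(cfg_b, "metformin", variant),
        ],
        ignore_index=True,
    )
    pooled = run_meta_pass(res)
    row = pooled[pooled["trait"] == trait].iloc[0]

    # the pipeline standardizes after batch correction, so the oracle's
    # factual SD must not contain batch-shift variance
    oracles = {
        cfg.name: oracle_trait_effect(
            cfg.replace(batch_sd=0.0), trait, "metformin", n=oracle_n, seed=seed + 777
        )
        for cfg in (cfg_a, cfg_b)
    }
    return RecoveryResult(
        trait=trait,
        pooled_beta=float(row["pooled_beta"]),
        pooled_se=float(row["pooled_se"]),
        oracle_effect=float(np.mean(list(oracles.values()))),
        per_cohort_oracle=oracles,
    )


def fdr_study(
    seed: int = 0,
    n_reps: int = 500,
    n_per_cohort: int = 250,
    medication: str = "metformin",
    q_cut: float = 0.05,
) -> dict:
    """Empirical FDR under the global null over replicate pipeline passes.

    Each replicate simulates two cohorts with NO planted effects, runs the
    full chain and counts BH discoveries at ``q_cut``; with no true effects
    every discovery is false, so the per-replicate false discovery
    proportion is V / max(R, 1) and the empirical FDR is its mean.
    """
    registry = load_registry()
    fdp = np.zeros(n_reps)
    n_discoveries = 0
    for rep in range(n_reps):
        s = seed + 1000 * rep
        cfg_a = diagene_like(seed=s, n_subjects=n_per_cohort)
        cfg_b = hoorn_like(seed=s + 1, n_subjects=n_per_cohort)
        res = pd.concat(
            [
                cohort_association_pass(cfg_a, medication, "full", registry),
                cohort_association_pass(cfg_b, medication, "full", registry),
            ],
            ignore_index=True,
        )
        pooled = run_meta_pass(res, q_cut=q_cut)
        r = int(pooled["significant"].sum())
        n_discoveries += r
        fdp[rep] = r / max(r, 1) if r > 0 else 0.0
    return {
        "empirical_fdr": float(fdp.mean()),
        "n_reps": n_reps,
        "total_discoveries": n_discoveries,
        "q_cut": q_cut,
    }
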