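"""Synthetic two-cohort plasma N-glycomics data with known ground truth.

Emulates the data structure of two type-2-diabetes cohorts: a clinical table
with realistic covariate distributions and confounded medication assignment
("confounding by indication": the probability of using a drug rises with the
covariates that indicate it), and a raw compositional abundance matrix from
a logistic-normal model — per-subject log-abundances are an analyte baseline
plus covariate effects, shared latent factors (block correlation by
structural family), planted medication effects on targeted analytes, batch
shifts and noise, then exponentiated.  Raw intensities are NOT normalized;
the preprocessing pipeline must do that.

Planted effects are shifts on the natural-log abundance scale of the
analytes matching a structural selector.  Because total-area normalization
couples analytes, the induced effect on any derived trait is defined by the
Monte-Carlo counterfactual oracle (:func:`oracle_trait_effect`), not by the
planted number.

Two presets mirror the published cohort characteristics: ``diagene_like``
(n=1815, 70-analyte panel, e.g. metformin 51.1%, SU 28.4%) and
``hoorn_like`` (n=1518, 68 analytes, metformin 68.3%).  Everything is
overridable; (config, seed) -> bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import clinical as clin
from .glycan import StructuralAnnotation, annotate_panel, parse_composition
from .preprocess import AbundanceMatrix
from .traits import TraitDefinition, compute_trait_matrix, load_registry, selector_matches

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticCohort",
    "diagene_like",
    "hoorn_like",
    "default_panel",
    "simulate_clinical",
    "simulate_abundances",
    "simulate_cohort",
    "oracle_trait_effect",
]


# --------------------------------------------------------------------------
# Panels

_PANEL_68 = [
    # high-mannose
    "H4N2", "H5N2", "H6N2", "H7N2", "H8N2",
    # hybrid
    "H6N3", "H6N3F1", "H6N3E1", "H7N3",
    # complex monoantennary (A1)
    "H3N3F1", "H4N3", "H4N3E1", "H4N3F1E1",
    # diantennary (A2)
    "H3N4", "H3N4F1", "H4N4", "H4N4F1", "H4N4E1", "H4N4F1E1", "H4N4L1",
    "H4N4F1L1", "H5N4", "H5N4F1", "H5N4E1", "H5N4F1E1", "H5N4E2",
    "H5N4F1E2", "H5N4L1", "H5N4F1L1", "H5N4L2", "H5N4F1L2", "H5N4E1L1",
    "H5N4F1E1L1",
    # bisected diantennary (A2B)
    "H4N5F1", "H5N5", "H5N5F1", "H5N5E1", "H5N5F1E1", "H5N5F1L1",
    # triantennary (A3)
    "H6N5", "H6N5F1", "H6N5E1", "H6N5F1E1", "H6N5E2", "H6N5L1", "H6N5F1L1",
    "H6N5E1L1", "H6N5E3", "H6N5L2", "H6N5F1E2",
    # bisected triantennary (A3B)
    "H6N6F1", "H6N6E1",
    # tetra-antennary (A4)
    "H7N6", "H7N6F1", "H7N6E1", "H7N6F1E1", "H7N6E2", "H7N6F1E2", "H7N6L1",
    "H7N6F1L1", "H7N6E1L1", "H7N6E2L1", "H7N6E3L1", "H7N6F1E2L1", "H7N6L2",
    "H7N6E4",
    # bisected tetra-antennary (A4B)
    "H7N7F1", "H7N7F1E1",
]

_PANEL_70 = _PANEL_68 + ["H9N2", "H7N3E1"]


def default_panel(size: int = 68) -> list[str]:
    """Representative composition panel (68 or 70 labels) covering every
    structural family the trait registry references."""
    if size == 68:
        return list(_PANEL_68)
    if size == 70:
        return list(_PANEL_70)
    raise ValueError("packaged panels come in sizes 68 and 70")


# --------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class PlantedEffect:
    """A medication effect on the log abundance of selected analytes."""

    medication: str
    selector: Mapping  # trait-registry selector dialect over annotations
    log_shift: float


@dataclass
class SimulationConfig:
    name: str
    n_subjects: int
    panel: list[str]
    covariates: dict  # distribution parameters, see presets
    med_prevalence: dict[str, float]
    med_confounding: dict[str, dict[str, float]]  # class -> {covariate: coef on z-scale}
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    n_batches: int = 4
    batch_sd: float = 0.08
    noise_sd: float = 0.40
    factor_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    missing_rate: float = 0.0  # MCAR rate on bmi/hba1c/hdl
    seed: int = 0

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _covariates_diagene() -> dict:
    return dict(
        male_frac=0.538,
        age=(65.21, 10.58),
        bmi=(30.46, 5.45),
        hba1c=(53.31, 11.58),
        duration=(10.04, 8.43),
        hdl=(1.71, 0.32),
        non_hdl=(2.58, 0.85),
        triglycerides=(1.70, 1.13),
        dbp=(82.0, 9.0),
        pulse_pressure=(50.0, 12.0),
        creatinine_male=(86.0, 0.22),  # lognormal: (median umol/L, sd of log)
        creatinine_female=(66.0, 0.22),
        smoking=(0.259, 0.562, 0.179),  # never, former, current
        cvd=0.346,
    )


def _covariates_hoorn() -> dict:
    return dict(
        male_frac=0.5626,
        age=(64.48, 10.63),
        bmi=(30.39, 5.40),
        hba1c=(50.63, 11.33),
        duration=(7.17, 5.81),
        hdl=(1.18, 0.39),
        non_hdl=(3.45, 1.40),
        triglycerides=(1.82, 1.05),
        dbp=(82.0, 9.5),
        pulse_pressure=(50.0, 12.5),
        creatinine_male=(79.0, 0.22),
        creatinine_female=(61.0, 0.22),
        smoking=(0.605, 0.213, 0.173),
        cvd=0.155,
    )


_CONFOUNDING = {
    "metformin": {"hba1c": 0.5, "bmi": 0.3, "duration": 0.2},
    "su": {"hba1c": 0.4, "duration": 0.2},
    "insulin": {"hba1c": 0.6, "duration": 0.5},
    "acei_arb": {"map": 0.5, "cvd": 0.4, "nephropathy": 0.5},
    "statin": {"cvd": 0.6, "non_hdl": 0.4, "age": 0.2},
}


def diagene_like(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        name="diagene-like",
        n_subjects=1815,
        panel=default_panel(70),
        covariates=_covariates_diagene(),
        med_prevalence={
            "metformin": 0.511,
            "su": 0.284,
            "insulin": 0.296,
            "acei_arb": 0.533,
            "statin": 0.644,
        },
        med_confounding=dict(_CONFOUNDING),
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


def hoorn_like(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        name="hoorn-like",
        n_subjects=1518,
        panel=default_panel(68),
        covariates=_covariates_hoorn(),
        med_prevalence={
            "metformin": 0.683,
            "su": 0.155,
            "insulin": 0.251,
            "acei_arb": 0.372,
            "statin": 0.696,
        },
        med_confounding=dict(_CONFOUNDING),
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


# --------------------------------------------------------------------------
# Clinical table

def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, sd**2 / shape if shape > 0 else 1.0


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept for which mean(sigmoid(a + lin)) == target prevalence."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if (1.0 / (1.0 + np.exp(-(mid + lin)))).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_clinical(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one cohort's clinical/medication table.

    Continuous covariates come from normal (age, BMI, HbA1c, blood-pressure
    components) or gamma (diabetes duration, triglycerides) families;
    medication flags from a logistic assignment model on standardized
    covariates, with the intercept calibrated to the target prevalence, so
    users and non-users differ systematically (confounding by indication).
    """
    n = config.n_subjects
    cv = config.covariates

    sex = np.where(rng.random(n) < cv["male_frac"], "male", "female")
    age = np.clip(rng.normal(*cv["age"], n), 19.0, 100.0)
    bmi = np.clip(rng.normal(*cv["bmi"], n), 16.0, 60.0)
    hba1c = np.clip(rng.normal(*cv["hba1c"], n), 20.0, 130.0)
    duration = rng.gamma(*_gamma_params(*cv["duration"]), n)
    hdl = np.clip(rng.normal(*cv["hdl"], n), 0.4, 4.0)
    non_hdl = np.clip(rng.normal(*cv["non_hdl"], n), 0.3, 9.0)
    total_chol = hdl + non_hdl
    trig = rng.gamma(*_gamma_params(*cv["triglycerides"]), n)
    dbp = np.clip(rng.normal(*cv["dbp"], n), 45.0, 130.0)
    sbp = dbp + rng.gamma(*_gamma_params(*cv["pulse_pressure"]), n)
    map_mmHg = np.array(
        [clin.mean_arterial_pressure(s, d) for s, d in zip(sbp, dbp)]
    )
    cre_med = np.where(sex == "male", cv["creatinine_male"][0], cv["creatinine_female"][0])
    creatinine = cre_med * np.exp(rng.normal(0.0, cv["creatinine_male"][1], n))
    egfr = np.array(
        [clin.egfr_mdrd(c, a, s) for c, a, s in zip(creatinine, age, sex)]
    )
    smk_p = np.asarray(cv["smoking"], dtype=float)
    smk_p = smk_p / smk_p.sum()  # printed cohort percentages may not sum to 100.0
    smoking = rng.choice(["never", "former", "current"], size=n, p=smk_p)
    cvd = rng.random(n) < cv["cvd"]

    # three-visit ACR histories; nephropathy derived through the clinical rule
    acr_mu = rng.normal(np.log(1.0), 1.0, n)
    acr = np.exp(acr_mu[:, None] + rng.normal(0.0, 0.3, (n, 3)))
    neph = np.array(
        [clin.nephropathy(acr[i], sex[i]) for i in range(n)], dtype=bool
    )

    df = pd.DataFrame(
        {
            "subject_id": [f"{config.name}-{i:05d}" for i in range(n)],
            "cohort": config.name,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "hba1c": hba1c,
            "hba1c_pct": hba1c / 10.929 + 2.15,
            "duration": duration,
            "hdl": hdl,
            "non_hdl": non_hdl,
            "total_chol": total_chol,
            "triglycerides": trig,
            "sbp": sbp,
            "dbp": dbp,
            "map": map_mmHg,
            "creatinine": creatinine,
            "egfr": egfr,
            "smoking": smoking,
            "cvd": cvd,
            "acr_1": acr[:, 0],
            "acr_2": acr[:, 1],
            "acr_3": acr[:, 2],
            "nephropathy": neph,
            "batch": rng.integers(0, config.n_batches, n).astype(str),
        }
    ).set_index("subject_id")

    zcols = {
        "age": _zscore(age),
        "bmi": _zscore(bmi),
        "hba1c": _zscore(hba1c),
        "duration": _zscore(duration),
        "non_hdl": _zscore(non_hdl),
        "map": _zscore(map_mmHg),
        "cvd": cvd.astype(float) - cvd.mean(),
        "nephropathy": neph.astype(float) - neph.mean(),
    }
    for med, target in config.med_prevalence.items():
        coefs = config.med_confounding.get(med, {})
        lin = np.zeros(n)
        for cov, coef in coefs.items():
            lin += coef * zcols[cov]
        a0 = _calibrate_intercept(lin, target)
        prob = 1.0 / (1.0 + np.exp(-(a0 + lin)))
        df[med] = rng.random(n) < prob

    if config.missing_rate > 0:
        for col in ("bmi", "hba1c", "hdl"):
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, col] = np.nan
    return df


# --------------------------------------------------------------------------
# Abundances

def _baseline_log_abundance(panel: list[str]) -> np.ndarray:
    """Deterministic per-analyte baseline log-abundances.

    A pure function of the panel (seeded jitter keyed on the panel itself,
    independent of the run seed), shaped so the abundance profile looks like
    total plasma: fully galactosylated sialylated diantennary species
    dominate, branching and under-galactosylation are penalized.
    """
    anns = annotate_panel(panel)
    base = np.zeros(len(panel))
    for i, lab in enumerate(panel):
        a = anns[lab]
        c = parse_composition(lab)
        if a.glycan_class == "complex":
            b = 3.0 - 1.1 * abs((a.antennarity or 2) - 2)
            b -= 0.6 * ((a.antennarity or 0) - (a.galactoses or 0))
            b -= 0.35 * ((a.galactoses or 0) - a.sialic_total)
            b += 0.25 * min(c.F, 1)
            if a.bisected:
                b -= 0.8
        elif a.glycan_class == "high_mannose":
            b = 1.0 - 0.35 * (c.H - 5)
        elif a.glycan_class == "hybrid":
            b = 0.0 - 0.3 * (c.H - 6)
        else:
            b = -1.0
        base[i] = b
    # panel-keyed jitter: stable digest, independent of the run seed, so a
    # given panel always has the same generative baseline profile
    import hashlib

    digest = hashlib.sha256("|".join(panel).encode()).digest()
    jitter_rng = np.random.default_rng(int.from_bytes(digest[:4], "little"))
    return base + jitter_rng.normal(0.0, 0.35, len(panel))


def _covariate_loadings(anns: dict[str, StructuralAnnotation], panel: list[str]):
    """Age/sex effects on log abundances (per SD of age; male vs female)."""
    age_l = np.zeros(len(panel))
    sex_l = np.zeros(len(panel))
    for i, lab in enumerate(panel):
        a = anns[lab]
        if a.glycan_class == "complex":
            gal_frac = (a.galactoses or 0) / (a.antennarity or 1)
            age_l[i] = 0.06 * bool(a.bisected) - 0.05 * gal_frac + 0.03 * (
                (a.antennarity or 2) - 2
            )
            sex_l[i] = 0.04 * min(a.F, 1) - 0.02 * a.sialic_total
        elif a.glycan_class == "high_mannose":
            age_l[i] = 0.03
    return age_l, sex_l


def _factor_loadings(anns, panel):
    """Latent-factor loadings giving block correlation by structural family."""
    lam = np.zeros((len(panel), 3))
    for i, lab in enumerate(panel):
        a = anns[lab]
        lam[i, 0] = 0.15 * min(a.F, 1)  # fucosylation capacity
        lam[i, 1] = 0.08 * a.sialic_total  # sialylation capacity
        if a.glycan_class == "complex":
            lam[i, 2] = 0.10 * ((a.antennarity or 2) - 2)  # branching
    return lam


def _effect_mask(selector: Mapping, anns, panel) -> np.ndarray:
    return np.array([selector_matches(selector, anns[lab]) for lab in panel])


def _log_abundances(
    clinical: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    med_override: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Subjects x analytes log-abundance matrix before exponentiation.

    ``med_override`` replaces medication indicator vectors (used by the
    counterfactual oracle); noise, factors and batch draws come from ``rng``.
    """
    panel = config.panel
    anns = annotate_panel(panel)
    bad = [lab for lab, a in anns.items() if a.glycan_class == "other" and not a.valid]
    if bad:
        raise ValueError(f"panel labels could not be annotated: {bad[:5]}")
    n, m = len(clinical), len(panel)

    log_x = np.tile(_baseline_log_abundance(panel), (n, 1))

    age_l, sex_l = _covariate_loadings(anns, panel)
    age_z = _zscore(clinical["age"].to_numpy(dtype=float))
    male = (clinical["sex"] == "male").to_numpy(dtype=float)
    log_x += np.outer(age_z, age_l) + np.outer(male, sex_l)

    lam = _factor_loadings(anns, panel)
    factors = rng.normal(0.0, 1.0, (n, 3)) * np.asarray(config.factor_sds)
    log_x += factors @ lam.T

    for eff in config.planted_effects:
        mask = _effect_mask(eff.selector, anns, panel)
        if med_override and eff.medication in med_override:
            users = np.asarray(med_override[eff.medication], dtype=float)
        else:
            users = clinical[eff.medication].to_numpy(dtype=float)
        log_x[:, mask] += eff.log_shift * users[:, None]

    batch_idx = clinical["batch"].astype(int).to_numpy()
    batch_shift = rng.normal(0.0, config.batch_sd, (config.n_batches, m))
    log_x += batch_shift[batch_idx]

    log_x += rng.normal(0.0, config.noise_sd, (n, m))
    log_x += rng.normal(0.0, 0.3, n)[:, None]  # per-subject MS signal scale
    return log_x


def simulate_abundances(
    clinical: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> AbundanceMatrix:
    """Raw (un-normalized) intensity matrix for one simulated cohort."""
    log_x = _log_abundances(clinical, config, rng)
    values = pd.DataFrame(np.exp(log_x), index=clinical.index, columns=config.panel)
    return AbundanceMatrix(values=values, batch=clinical["batch"], stage="raw")


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    abundances: AbundanceMatrix
    truth: dict  # planted effects + config, enough to recompute oracle effects


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """One full synthetic cohort: clinical table, raw abundances, truth record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    clinical = simulate_clinical(config, rng)
    abundances = simulate_abundances(clinical, config, rng)
    truth = {
        "config_name": config.name,
        "planted_effects": [
            {"medication": e.medication, "selector": dict(e.selector), "log_shift": e.log_shift}
            for e in config.planted_effects
        ],
        "seed": config.seed if seed is None else seed,
    }
    return SyntheticCohort(clinical=clinical, abundances=abundances, truth=truth)


# --------------------------------------------------------------------------
# Ground-truth oracle

def oracle_trait_effect(
    config: SimulationConfig,
    trait: str | TraitDefinition,
    medication: str,
    n: int = 200_000,
    seed: int = 12345,
    registry: list[TraitDefinition] | None = None,
) -> float:
    """Monte-Carlo ground truth: standardized counterfactual trait effect.

    Simulates ``n`` subjects from the covariate/assignment model, then
    evaluates each subject's normalized trait value twice — medication
    forced on and forced off, with identical noise — and returns the mean
    paired difference divided by the SD of the trait under the factual
    (observed-assignment) data.  This is what a correctly adjusted
    regression of the standardized trait on the medication indicator should
    recover.  Renormalization coupling is automatically included: an effect
    planted on one analyte family moves every trait that shares abundance
    mass with it.
    """
    if registry is None:
        registry = load_registry()
    if isinstance(trait, str):
        matches = [t for t in registry if t.name == trait]
        if not matches:
            raise KeyError(f"trait {trait!r} not in registry")
        tdef = matches[0]
    else:
        tdef = trait

    big = config.replace(n_subjects=n)
    rng = np.random.default_rng(seed)
    clinical = simulate_clinical(big, rng)
    anns = annotate_panel(big.panel)

    # one noise realisation, three medication assignments
    noise_state = rng.bit_generator.state
    ones = np.ones(len(clinical))
    zeros = np.zeros(len(clinical))

    def trait_values(med_vec) -> np.ndarray:
        r = np.random.default_rng()
        r.bit_generator.state = noise_state
        log_x = _log_abundances(clinical, big, r, med_override={medication: med_vec})
        x = np.exp(log_x)
        x /= x.sum(axis=1, keepdims=True)
        tm = compute_trait_matrix(
            pd.DataFrame(x, index=clinical.index, columns=big.panel), anns, [tdef]
        )
        return tm[tdef.name].to_numpy()

    factual = clinical[medication].to_numpy(dtype=float)
    t_obs = trait_values(factual)
    t_on = trait_values(ones)
    t_off = trait_values(zeros)
    sd = np.nanstd(t_obs, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return float("nan")
    return float(np.nanmean(t_on - t_off) / sd)
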