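"""Pipeline orchestration: config validation, stage sequencing, provenance.

The stage order is fixed — QC -> total-area normalization -> batch
correction -> derived traits -> per-cohort standardization -> association
models -> random-effects meta-analysis -> BH — and cohorts are processed
strictly independently until the meta stage.  Every output file carries
'#'-prefixed provenance header lines (package version, config hash, seed,
stage), and re-running with the same config and inputs reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .glycan import annotate_panel, load_override_table
from .meta import run_meta_pass
from .models import build_model_spec, fit_linear_many
from .preprocess import (
    AbundanceMatrix,
    batch_correct,
    normalize_total_area,
    qc_filter,
    standardize,
)
from .traits import compute_trait_matrix, load_registry

__all__ = [
    "RunConfig",
    "CohortInput",
    "ConfigError",
    "DataError",
    "validate_config",
    "run_pipeline",
    "write_tsv",
    "read_tsv",
]

log = logging.getLogger("glycomeds")

STAGE_ORDER = ["qc", "normalize", "batch_correct", "traits", "associate", "meta"]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class CohortInput:
    name: str
    abundances: Path
    clinical: Path


@dataclass
class RunConfig:
    cohorts: list[CohortInput]
    output_dir: Path
    registry: Path | None = None
    annotation_overrides: Path | None = None
    medications: list[str] = field(default_factory=lambda: ["metformin"])
    model_variant: str = "full"
    min_median_rel: float = 1e-4
    min_detect_rate: float = 0.5
    bh_family: str = "per_medication"
    q_cut: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "cohorts": [(c.name, str(c.abundances), str(c.clinical)) for c in self.cohorts],
                "registry": str(self.registry),
                "overrides": str(self.annotation_overrides),
                "medications": self.medications,
                "variant": self.model_variant,
                "qc": [self.min_median_rel, self.min_detect_rate],
                "bh": [self.bh_family, self.q_cut],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML run config; ALL errors are collected."""
    import yaml

    errors: list[str] = []
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    except Exception as exc:
        return None, [f"cannot read config {path}: {exc}"]

    cohorts: list[CohortInput] = []
    raw_cohorts = doc.get("cohorts") or []
    if len(raw_cohorts) < 1:
        errors.append("config needs at least one cohort entry")
    for i, c in enumerate(raw_cohorts):
        name = c.get("name", f"cohort{i}")
        for key in ("abundances", "clinical"):
            if key not in c:
                errors.append(f"cohort {name}: missing {key} path")
            elif not Path(c[key]).exists():
                errors.append(f"cohort {name}: {key} file {c[key]} does not exist")
        if "abundances" in c and "clinical" in c:
            cohorts.append(CohortInput(name, Path(c["abundances"]), Path(c["clinical"])))

    for key in ("registry", "annotation_overrides"):
        if doc.get(key) and not Path(doc[key]).exists():
            errors.append(f"{key} file {doc[key]} does not exist")

    q_cut = doc.get("q_cut", 0.05)
    if not (0 < q_cut < 1):
        errors.append(f"q_cut must be in (0, 1), got {q_cut}")
    bh_family = doc.get("bh_family", "per_medication")
    if bh_family not in ("per_medication", "global"):
        errors.append(f"unknown bh_family {bh_family!r}")
    variant = doc.get("model_variant", "full")
    from .models import VARIANTS

    if variant not in VARIANTS:
        errors.append(f"unknown model_variant {variant!r}")
    meds = doc.get("medications", ["metformin"])
    from .clinical import MED_CLASSES

    for m in meds:
        if m not in MED_CLASSES:
            errors.append(f"unknown medication class {m!r}")

    if "output_dir" not in doc:
        errors.append("config needs output_dir")
    if errors:
        return None, errors
    return (
        RunConfig(
            cohorts=cohorts,
            output_dir=Path(doc["output_dir"]),
            registry=Path(doc["registry"]) if doc.get("registry") else None,
            annotation_overrides=(
                Path(doc["annotation_overrides"]) if doc.get("annotation_overrides") else None
            ),
            medications=list(meds),
            model_variant=variant,
            min_median_rel=float(doc.get("min_median_rel", 1e-4)),
            min_detect_rate=float(doc.get("min_detect_rate", 0.5)),
            bh_family=bh_family,
            q_cut=float(q_cut),
            seed=int(doc.get("seed", 0)),
            log_level=str(doc.get("log_level", "INFO")),
        ),
        [],
    )


def write_tsv(df: pd.DataFrame, path: Path, provenance: dict, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# glycomeds {__version__}\n")
        for k, v in sorted(provenance.items()):
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc


def _load_cohort(ci: CohortInput) -> tuple[AbundanceMatrix, pd.DataFrame]:
    clinical = read_tsv(ci.clinical)
    values = read_tsv(ci.abundances)
    if "batch" in values.columns:
        batch = values.pop("batch").astype(str)
    elif "batch" in clinical.columns:
        batch = clinical["batch"].astype(str).reindex(values.index)
    else:
        raise DataError(f"cohort {ci.name}: no batch column in abundances or clinical")
    if (values.to_numpy() < 0).any():
        raise DataError(f"cohort {ci.name}: negative raw intensities")
    return AbundanceMatrix(values=values, batch=batch, stage="raw"), clinical


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Execute the stage sequence; returns a bundle of result tables.

    ``stop_after`` ends the run after a named stage (e.g. "traits" writes
    the trait matrices and fits no models).  Any stage failure raises with
    the stage and cohort named.
    """
    if stop_after is not None and stop_after not in STAGE_ORDER:
        raise ConfigError(f"unknown stage {stop_after!r}; stages: {STAGE_ORDER}")
    out = Path(config.output_dir)
    prov = {"config_hash": config.config_hash(), "seed": config.seed}
    registry = load_registry(config.registry)
    overrides = (
        load_override_table(config.annotation_overrides)
        if config.annotation_overrides
        else None
    )

    bundle: dict = {"traits": {}, "qc_reports": {}}
    cohort_results = []
    for ci in config.cohorts:
        stage = "load"
        try:
            m, clinical = _load_cohort(ci)
            stage = "qc"
            m, report = qc_filter(m, config.min_median_rel, config.min_detect_rate)
            write_tsv(
                report.to_frame(),
                out / f"{ci.name}.qc_report.tsv",
                {**prov, "stage": "qc", "cohort": ci.name},
                index=False,
            )
            bundle["qc_reports"][ci.name] = report
            if stop_after == "qc":
                continue
            stage = "normalize"
            m = normalize_total_area(m)
            write_tsv(m.values, out / f"{ci.name}.normalized.tsv", {**prov, "stage": "normalize", "cohort": ci.name})
            if stop_after == "normalize":
                continue
            stage = "batch_correct"
            m = batch_correct(m)
            write_tsv(m.values, out / f"{ci.name}.batch_corrected.tsv", {**prov, "stage": "batch_correct", "cohort": ci.name})
            if stop_after == "batch_correct":
                continue
            stage = "traits"
            anns = annotate_panel(m.values.columns, overrides)
            tm = compute_trait_matrix(m.values, anns, registry)
            write_tsv(
                tm,
                out / f"{ci.name}.traits.tsv",
                {**prov, "stage": "traits", "cohort": ci.name, **tm.attrs.get("provenance", {})},
            )
            bundle["traits"][ci.name] = tm
            if stop_after == "traits":
                continue
            stage = "associate"
            tm_std = standardize(tm)
            for med in config.medications:
                spec = build_model_spec(med, config.model_variant)
                results = fit_linear_many(tm_std, clinical, spec, cohort=ci.name)
                cohort_results.extend(r.as_dict() for r in results)
        except Exception as exc:
            raise DataError(f"stage {stage!r}, cohort {ci.name!r}: {exc}") from exc

    if stop_after in ("qc", "normalize", "batch_correct", "traits"):
        return bundle
    per_cohort = pd.DataFrame(cohort_results)
    bundle["associations"] = per_cohort
    write_tsv(
        per_cohort,
        out / "associations.tsv",
        {**prov, "stage": "associate", "variant": config.model_variant},
        index=False,
    )
    if stop_after == "associate":
        return bundle

    pooled = run_meta_pass(per_cohort, q_cut=config.q_cut, family=config.bh_family)
    desc = {t.name: t.description for t in registry}
    pooled.insert(3, "description", pooled["trait"].map(desc))
    bundle["meta"] = pooled
    write_tsv(
        pooled,
        out / "meta_results.tsv",
        {**prov, "stage": "meta", "bh_family": config.bh_family, "q_cut": config.q_cut},
        index=False,
    )
    return bundle
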