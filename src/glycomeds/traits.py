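"""Derived glycosylation traits from annotated direct compositions.

A derived trait summarises a structural family of direct glycan analytes as
a weighted ratio

    value = sum_{i in numerator} w_i * x_i / sum_{j in denominator} x_j

on total-area-normalized abundances x.  Unit weights give "X within Y"
fractions (e.g. A2F, the fucosylated fraction of diantennary glycans);
per-antenna and per-galactose weights give feature averages (e.g. A2E, the
mean number of alpha2,6-sialic acids per antenna across diantennary
glycans).  The trait definitions are data, not code: they live in a
reviewed registry file (``data/trait_registry.yaml``, 45 traits).

Analytes flagged ``valid=False`` by annotation never enter numerators or
denominators.  An empty or zero denominator yields a missing value, never 0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .glycan import StructuralAnnotation

__all__ = [
    "TraitDefinition",
    "RegistryError",
    "load_registry",
    "default_registry_path",
    "selector_matches",
    "compute_trait",
    "compute_trait_matrix",
]

_SELECTOR_KEYS = {
    "all",
    "class",
    "antennarity",
    "bisected",
    "fucosylated",
    "E",
    "L",
    "S",
    "G",
    "F",
}
_WEIGHTS = {
    "unit",
    "G/antenna",
    "S/antenna",
    "E/antenna",
    "L/antenna",
    "S/galactose",
    "E/galactose",
    "L/galactose",
}


class RegistryError(ValueError):
    """Malformed or inconsistent trait registry."""


@dataclass(frozen=True)
class TraitDefinition:
    name: str
    description: str
    numerator: Mapping
    denominator: Mapping
    weight: str = "unit"
    ratio: bool = False  # ratio traits (e.g. MHy) are exempt from the
    # numerator-subset and [0,1] range expectations
    registry_completion: bool = False

    def __post_init__(self):
        if self.weight not in _WEIGHTS:
            raise RegistryError(f"trait {self.name}: unknown weight {self.weight!r}")
        for sel in (self.numerator, self.denominator):
            bad = set(sel) - _SELECTOR_KEYS
            if bad:
                raise RegistryError(
                    f"trait {self.name}: unknown selector field(s) {sorted(bad)}"
                )


def default_registry_path() -> Path:
    return Path(resources.files("glycomeds") / "data" / "trait_registry.yaml")


def load_registry(path: str | Path | None = None) -> list[TraitDefinition]:
    """Load trait definitions in file order; names must be unique."""
    p = Path(path) if path is not None else default_registry_path()
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "traits" not in doc:
        raise RegistryError(f"{p}: registry file needs a top-level 'traits' list")
    defs: list[TraitDefinition] = []
    seen: set[str] = set()
    for entry in doc["traits"]:
        name = entry.get("name")
        if not name:
            raise RegistryError(f"{p}: trait entry without a name")
        if name in seen:
            raise RegistryError(f"{p}: duplicate trait name {name!r}")
        seen.add(name)
        defs.append(
            TraitDefinition(
                name=name,
                description=entry.get("description", ""),
                numerator=entry.get("numerator", {}),
                denominator=entry.get("denominator", {}),
                weight=entry.get("weight", "unit"),
                ratio=bool(entry.get("ratio", False)),
                registry_completion=bool(entry.get("registry_completion", False)),
            )
        )
    return defs


def _match_count(constraint, value: int) -> bool:
    if constraint == "1+":
        return value >= 1
    return value == int(constraint)


def selector_matches(sel: Mapping, ann: StructuralAnnotation) -> bool:
    """Does one annotated analyte satisfy a selector?  Invalid analytes never match."""
    if not ann.valid:
        return False
    if sel.get("all"):
        return True
    if "class" in sel:
        cls = sel["class"]
        classes = cls if isinstance(cls, list) else [cls]
        if ann.glycan_class not in classes:
            return False
    if "antennarity" in sel:
        if ann.antennarity is None or ann.antennarity != int(sel["antennarity"]):
            return False
    if "bisected" in sel and bool(ann.bisected) != bool(sel["bisected"]):
        return False
    if "fucosylated" in sel and ann.fucosylated != bool(sel["fucosylated"]):
        return False
    for key, value in (("E", ann.E), ("L", ann.L), ("S", ann.sialic_total), ("F", ann.F)):
        if key in sel and not _match_count(sel[key], value):
            return False
    if "G" in sel:
        if ann.galactoses is None or not _match_count(sel["G"], ann.galactoses):
            return False
    return True


def _weight_value(weight: str, ann: StructuralAnnotation) -> float | None:
    """Per-analyte weight; None means the analyte is excluded (per-galactose on G==0)."""
    if weight == "unit":
        return 1.0
    feature, _, per = weight.partition("/")
    num = {"G": ann.galactoses, "S": ann.sialic_total, "E": ann.E, "L": ann.L}[feature]
    if per == "antenna":
        if ann.antennarity is None or ann.antennarity == 0 or num is None:
            return None
        return num / ann.antennarity
    if ann.galactoses is None or ann.galactoses == 0 or num is None:
        return None  # per-galactose average undefined for agalactosylated species
    return num / ann.galactoses


def _trait_masks(
    t: TraitDefinition,
    annotations: Mapping[str, StructuralAnnotation],
    analytes: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numerator mask, weights and denominator mask over the analyte axis."""
    num_mask = np.zeros(len(analytes), dtype=bool)
    den_mask = np.zeros(len(analytes), dtype=bool)
    w = np.zeros(len(analytes), dtype=float)
    for i, a in enumerate(analytes):
        ann = annotations[a]
        in_den = selector_matches(t.denominator, ann)
        in_num = selector_matches(t.numerator, ann)
        if in_num or in_den:
            wi = _weight_value(t.weight, ann)
            if wi is None:
                continue  # excluded from both sums (e.g. G==0 under per-galactose)
            if in_num:
                num_mask[i] = True
                w[i] = wi
            if in_den:
                den_mask[i] = True
    if t.weight == "unit" and not t.ratio and (num_mask & ~den_mask).any():
        extra = [analytes[i] for i in np.nonzero(num_mask & ~den_mask)[0]]
        raise RegistryError(
            f"trait {t.name}: numerator selects analytes outside the denominator: {extra}"
        )
    return num_mask, w, den_mask


def compute_trait(
    t: TraitDefinition,
    row: pd.Series,
    annotations: Mapping[str, StructuralAnnotation],
) -> float:
    """One trait value for one subject's normalized abundance row."""
    analytes = list(row.index)
    missing = [a for a in analytes if a not in annotations]
    if missing:
        raise KeyError(f"no annotation for analyte(s) {missing[:5]}")
    num_mask, w, den_mask = _trait_masks(t, annotations, analytes)
    x = row.to_numpy(dtype=float)
    den = x[den_mask].sum()
    if not den_mask.any() or den == 0 or not np.isfinite(den):
        return float("nan")
    return float((x[num_mask] * w[num_mask]).sum() / den)


def compute_trait_matrix(
    values: pd.DataFrame,
    annotations: Mapping[str, StructuralAnnotation],
    registry: list[TraitDefinition],
) -> pd.DataFrame:
    """Subjects x traits matrix from a normalized abundance matrix.

    Vectorized across subjects: each trait reduces to two masked matrix-vector
    products.  Row order is preserved; ``attrs['provenance']`` records the
    registry size and a hash of the analyte panel.
    """
    analytes = list(values.columns)
    missing = [a for a in analytes if a not in annotations]
    if missing:
        raise KeyError(f"no annotation for analyte(s) {missing[:5]}")
    X = values.to_numpy(dtype=float)
    out = {}
    for t in registry:
        num_mask, w, den_mask = _trait_masks(t, annotations, analytes)
        if not den_mask.any():
            out[t.name] = np.full(len(values), np.nan)
            continue
        den = X[:, den_mask].sum(axis=1)
        num = X[:, num_mask] @ w[num_mask] if num_mask.any() else np.zeros(len(values))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[t.name] = vals
    tm = pd.DataFrame(out, index=values.index)
    panel_hash = hashlib.sha1("|".join(analytes).encode()).hexdigest()[:12]
    tm.attrs["provenance"] = {"n_traits": len(registry), "panel_hash": panel_hash}
    return tm
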