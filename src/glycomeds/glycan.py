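"""Glycan composition parsing and structural annotation.

Direct plasma N-glycan analytes are named by monosaccharide counts:
hexoses (H), N-acetylhexosamines (N), fucoses (F) and sialic acids split by
linkage after linkage-specific derivatization — alpha2,6-linked (E) and
alpha2,3-linked (L).  Every derived glycosylation trait is defined over the
structural features inferred here: glycan class (high-mannose / hybrid /
complex), antennarity, bisecting GlcNAc, fucosylation, galactosylation and
sialylation.

Composition alone does not determine structure; the rules below encode the
standard total-plasma-N-glycome reading (tri/tetra-antennary plasma species
are near-fully galactosylated, so complex glycans with an extra HexNAc but
low hexose count are read as bisected IgG-type structures).  Any label can be
re-annotated through an override table when orthogonal evidence exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "GlycanComposition",
    "StructuralAnnotation",
    "GlycanParseError",
    "AnnotationConfigError",
    "parse_composition",
    "format_composition",
    "annotate",
    "annotate_panel",
    "load_override_table",
]

_COMPOSITION_RE = re.compile(
    r"^H(?P<H>\d+)N(?P<N>\d+)(?:F(?P<F>\d+))?(?:E(?P<E>\d+))?(?:L(?P<L>\d+))?$"
)


class GlycanParseError(ValueError):
    """Raised when a composition string does not match the H/N/F/E/L grammar."""


class AnnotationConfigError(ValueError):
    """Raised when an override annotation table is internally inconsistent."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one direct glycan analyte.

    H: hexoses, N: N-acetylhexosamines, F: fucoses,
    E: alpha2,6-linked sialic acids, L: alpha2,3-linked sialic acids.
    """

    H: int
    N: int
    F: int = 0
    E: int = 0
    L: int = 0
    label: str = ""

    def __post_init__(self):
        for letter in "HNFEL":
            v = getattr(self, letter)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"count {letter}={v!r} must be a non-negative integer")
        if not self.label:
            object.__setattr__(self, "label", format_composition(self))

    @property
    def sialic_total(self) -> int:
        return self.E + self.L


def parse_composition(s: str) -> GlycanComposition:
    """Parse a composition string like ``"H5N4F1E2"`` into counts.

    Letters appear in the fixed order H, N, F, E, L; H and N are mandatory,
    the rest default to zero.  A present letter must carry a count >= 1.
    """
    m = _COMPOSITION_RE.match(s.strip())
    if m is None:
        bad = re.search(r"[^HNFEL0-9]", s.strip())
        if bad:
            raise GlycanParseError(
                f"composition {s!r}: unknown or misplaced token {bad.group(0)!r}"
            )
        raise GlycanParseError(
            f"composition {s!r} does not match the grammar H<i>N<i>[F<i>][E<i>][L<i>]"
        )
    counts = {k: int(v) if v is not None else 0 for k, v in m.groupdict().items()}
    for letter in ("F", "E", "L"):
        token = f"{letter}{counts[letter]}"
        if token in s and counts[letter] == 0:
            raise GlycanParseError(f"composition {s!r}: zero count on token {token!r}")
    if counts["H"] == 0 or counts["N"] == 0:
        raise GlycanParseError(f"composition {s!r}: H and N counts must be >= 1")
    return GlycanComposition(label=s.strip(), **counts)


def format_composition(c: GlycanComposition) -> str:
    out = f"H{c.H}N{c.N}"
    for letter in ("F", "E", "L"):
        v = getattr(c, letter)
        if v:
            out += f"{letter}{v}"
    return out


@dataclass(frozen=True)
class StructuralAnnotation:
    """Structural features inferred from a composition.

    ``antennarity``, ``bisected`` and ``galactoses`` are defined for complex
    glycans only and are ``None`` otherwise.  ``valid`` is False when the
    inferred features are internally inconsistent (e.g. more sialic acids
    than galactoses); invalid analytes are excluded from trait denominators
    rather than raising, so one bad analyte cannot abort a run.
    """

    label: str
    glycan_class: str  # high_mannose | hybrid | complex | other
    antennarity: int | None
    bisected: bool | None
    fucosylated: bool
    galactoses: int | None
    sialic_total: int
    valid: bool
    F: int = 0
    E: int = 0
    L: int = 0


def _annotate_rules(c: GlycanComposition) -> StructuralAnnotation:
    """Apply the composition -> structure rule set (no overrides)."""
    cls: str
    ant: int | None = None
    bis: bool | None = None
    gal: int | None = None
    valid = True

    if c.N == 2:
        cls = "high_mannose" if c.H >= 4 else "other"
    elif c.N == 3 and c.H >= 6:
        cls = "hybrid"
    elif c.N >= 3:
        cls = "complex"
        a_raw = c.N - 2
        if a_raw <= 2:
            ant, bis = a_raw, False
        elif a_raw == 3:
            # extra HexNAc on an under-galactosylated backbone reads as a
            # bisected diantennary rather than a bare triantennary
            ant, bis = (2, True) if c.H <= 5 else (3, False)
        elif a_raw == 4:
            ant, bis = (3, True) if c.H <= 6 else (4, False)
        elif a_raw == 5:
            ant, bis = 4, True
        else:
            ant, bis, valid = 4, True, False  # beyond tetra-antennary: flag
        gal = c.H - 3
        if gal < 0 or gal > ant or c.sialic_total > gal:
            valid = False
    else:
        cls = "other"
        valid = False

    if cls in ("high_mannose", "other") and (c.F or c.sialic_total):
        # fucosylated or sialylated oligomannose composition is inconsistent
        valid = False

    return StructuralAnnotation(
        label=c.label,
        glycan_class=cls,
        antennarity=ant,
        bisected=bis,
        fucosylated=c.F >= 1,
        galactoses=gal,
        sialic_total=c.sialic_total,
        valid=valid,
        F=c.F,
        E=c.E,
        L=c.L,
    )


def annotate(
    c: GlycanComposition,
    overrides: Mapping[str, StructuralAnnotation] | None = None,
) -> StructuralAnnotation:
    """Annotate one composition; an override-table entry wins over the rules.

    Consistency is re-checked after override assignment: a complex annotation
    with sialic_total > galactoses or galactoses > antennarity is returned
    with ``valid=False`` rather than raising.
    """
    if overrides and c.label in overrides:
        ov = overrides[c.label]
        valid = True
        if ov.glycan_class == "complex":
            if ov.antennarity is None or not (1 <= ov.antennarity <= 4):
                raise AnnotationConfigError(
                    f"override for {c.label}: complex annotation needs antennarity 1-4"
                )
            gal = ov.galactoses if ov.galactoses is not None else c.H - 3
            if gal < 0 or gal > ov.antennarity or c.sialic_total > gal:
                valid = False
            return StructuralAnnotation(
                label=c.label,
                glycan_class="complex",
                antennarity=ov.antennarity,
                bisected=bool(ov.bisected),
                fucosylated=ov.fucosylated,
                galactoses=gal,
                sialic_total=c.sialic_total,
                valid=valid,
                F=c.F,
                E=c.E,
                L=c.L,
            )
        return StructuralAnnotation(
            label=c.label,
            glycan_class=ov.glycan_class,
            antennarity=None,
            bisected=None,
            fucosylated=ov.fucosylated,
            galactoses=None,
            sialic_total=c.sialic_total,
            valid=ov.valid,
            F=c.F,
            E=c.E,
            L=c.L,
        )
    return _annotate_rules(c)


def annotate_panel(
    labels,
    overrides: Mapping[str, StructuralAnnotation] | None = None,
) -> dict[str, StructuralAnnotation]:
    """Parse and annotate a whole panel of composition labels."""
    return {lab: annotate(parse_composition(lab), overrides) for lab in labels}


def load_override_table(path: str | Path) -> dict[str, StructuralAnnotation]:
    """Read an override annotation TSV (label, class, antennarity, bisected, fucosylated).

    Empty cells in antennarity/bisected mean "not applicable" (non-complex
    classes).  Inconsistent rows raise :class:`AnnotationConfigError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"label", "class"}
    if not required.issubset(df.columns):
        raise AnnotationConfigError(f"override table needs columns {sorted(required)}")
    out: dict[str, StructuralAnnotation] = {}
    for _, row in df.iterrows():
        label = row["label"].strip()
        cls = row["class"].strip()
        if label in out:
            raise AnnotationConfigError(f"duplicate override for {label}")
        if cls not in {"high_mannose", "hybrid", "complex", "other"}:
            raise AnnotationConfigError(f"override for {label}: unknown class {cls!r}")
        ant = int(row["antennarity"]) if row.get("antennarity", "") else None
        bis = (
            row.get("bisected", "").strip().lower() in {"1", "true", "yes"}
            if row.get("bisected", "")
            else None
        )
        fuc = row.get("fucosylated", "").strip().lower() in {"1", "true", "yes"}
        if cls == "complex" and ant is None:
            raise AnnotationConfigError(
                f"override for {label}: complex class requires antennarity"
            )
        out[label] = StructuralAnnotation(
            label=label,
            glycan_class=cls,
            antennarity=ant,
            bisected=bis,
            fucosylated=fuc,
            galactoses=None,
            sialic_total=0,
            valid=cls != "other",
        )
    return out
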