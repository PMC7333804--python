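"""Analyte QC, total-area normalization, batch correction and standardization.

Raw MS intensities for released plasma N-glycans carry no absolute scale, so
each subject's analyte intensities are divided by their sum ("total-area
normalization"), making the data compositional.  Batch correction operates on
the log scale with per-batch median centering — robust, and safe on
compositional data because rows are renormalized afterwards.  Outcome
standardization (mean 0, SD 1 per column, per cohort) puts regression betas
on the SD scale.

Stages are tracked explicitly and transitions are monotone:
raw -> qc_passed -> normalized -> batch_corrected -> standardized.
Out-of-order calls raise :class:`StageError`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "QCReport",
    "StageError",
    "PreprocessError",
    "qc_filter",
    "normalize_total_area",
    "batch_correct",
    "standardize",
]

STAGES = ["raw", "qc_passed", "normalized", "batch_corrected", "standardized"]


class StageError(RuntimeError):
    """A preprocessing operation was called out of pipeline order."""


class PreprocessError(ValueError):
    """Degenerate input (zero rows, constant columns, ...)."""


@dataclass
class AbundanceMatrix:
    """Subjects x analytes abundance table with batch labels and a stage tag."""

    values: pd.DataFrame  # index: subject ids, columns: composition labels
    batch: pd.Series  # aligned to values.index
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.batch = self.batch.reindex(self.values.index)
        if self.batch.isna().any():
            missing = self.batch.index[self.batch.isna()].tolist()[:5]
            raise ValueError(f"subjects without batch label: {missing}")
        if self.stage != "standardized" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances before standardization")

    def _require(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is at {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str) -> "AbundanceMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"stage cannot go back from {self.stage!r} to {stage!r}")
        return dataclasses.replace(self, values=values, stage=stage)


@dataclass
class QCReport:
    """Every exclusion (analyte or subject) with its reason."""

    excluded_analytes: list[tuple[str, str]] = field(default_factory=list)
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("analyte", n, r) for n, r in self.excluded_analytes]
        rows += [("subject", str(s), r) for s, r in self.excluded_subjects]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


def qc_filter(
    m: AbundanceMatrix,
    min_median_rel: float = 1e-4,
    min_detect_rate: float = 0.5,
    exclude: list[str] | None = None,
) -> tuple[AbundanceMatrix, QCReport]:
    """Drop low-intensity / poorly detected analytes and zero-signal subjects.

    An analyte is kept when its median relative intensity (within-subject
    fraction of total signal) is >= ``min_median_rel`` and it is detected
    (value > 0) in at least ``min_detect_rate`` of subjects.  ``exclude``
    lists analytes removed a priori (e.g. known spectral interferences).
    """
    m._require("raw")
    report = QCReport()
    vals = m.values.copy()

    row_tot = vals.sum(axis=1)
    dead = row_tot == 0
    for s in vals.index[dead]:
        report.excluded_subjects.append((s, "total intensity is zero"))
    vals = vals.loc[~dead]
    if vals.empty:
        raise PreprocessError("all subjects excluded by QC")

    rel = vals.div(vals.sum(axis=1), axis=0)
    keep = []
    for a in vals.columns:
        if exclude and a in exclude:
            report.excluded_analytes.append((a, "on explicit exclusion list"))
            continue
        med = float(rel[a].median())
        det = float((vals[a] > 0).mean())
        if med < min_median_rel:
            report.excluded_analytes.append(
                (a, f"median relative intensity {med:.3g} < {min_median_rel:g}")
            )
        elif det < min_detect_rate:
            report.excluded_analytes.append(
                (a, f"detection rate {det:.3g} < {min_detect_rate:g}")
            )
        else:
            keep.append(a)
    if not keep:
        raise PreprocessError("all analytes excluded by QC")
    return m.with_values(vals[keep], "qc_passed"), report


def normalize_total_area(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each subject's row by its row sum; rows then sum to 1."""
    m._require("qc_passed")
    tot = m.values.sum(axis=1)
    zero = tot == 0
    if zero.any():
        raise PreprocessError(
            f"zero total intensity for subject(s) {m.values.index[zero].tolist()[:5]}"
        )
    return m.with_values(m.values.div(tot, axis=0), "normalized")


def batch_correct(m: AbundanceMatrix) -> AbundanceMatrix:
    """Per-analyte log-scale median centering within batch.

    Log abundances are centered on their batch median and re-centered to the
    global median, back-transformed and renormalized to row sum 1.  Because
    renormalization perturbs the alignment, the center-and-renormalize step
    is iterated to its fixed point, at which per-batch medians of every
    analyte agree exactly AND rows sum to 1.  Zeros are replaced by half the
    smallest positive value of that analyte before the log transform.
    Single-batch input and batches with < 2 subjects pass through unchanged
    (the latter with a warning).
    """
    m._require("normalized")
    batches = m.batch.unique()
    if len(batches) == 1:
        return m.with_values(m.values, "batch_corrected")

    vals = m.values.to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        pos = col[col > 0]
        if pos.size == 0:
            continue
        col[col == 0] = pos.min() / 2.0
        vals[:, j] = col

    small_batches = [b for b in batches if (m.batch == b).sum() < 2]
    big = [b for b in batches if b not in small_batches]
    masks = {b: (m.batch == b).to_numpy() for b in big}

    # renormalization perturbs the aligned medians, so iterate the
    # center-and-renormalize step to its fixed point
    # clean batch structure converges geometrically; heterogeneous noisy data
    # reaches an irreducible floor (row-sum coupling), detected as no progress
    out = vals / vals.sum(axis=1, keepdims=True)
    prev_shift = np.inf
    for _ in range(200):
        log = np.log(out)
        global_med = np.median(log, axis=0)
        shift = 0.0
        for b in big:
            idx = masks[b]
            batch_med = np.median(log[idx], axis=0)
            delta = batch_med - global_med
            log[idx] -= delta
            shift = max(shift, float(np.abs(delta).max()))
        out = np.exp(log)
        out /= out.sum(axis=1, keepdims=True)
        if shift < 1e-13 or shift > 0.7 * prev_shift:
            break
        prev_shift = shift
    corrected = m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        "batch_corrected",
    )
    if small_batches:
        import warnings

        warnings.warn(
            f"batches with <2 subjects passed through uncorrected: {small_batches}",
            stacklevel=2,
        )
    return corrected


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sample SD (n-1) 1.

    Applied per cohort, never on pooled cohorts.  Missing values are ignored
    in the moments and propagate.  A zero-variance column raises, naming it.
    """
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise PreprocessError(f"column {col!r} has zero or undefined variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)
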