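"""Derived clinical covariates and descriptive cohort comparisons.

Covers the covariate derivations every association model relies on: mean
arterial pressure, non-HDL cholesterol, eGFR by the 4-variable MDRD study
equation, the diabetic-nephropathy rule on albumin/creatinine-ratio (ACR)
histories, medication-class flags from ATC codes, and group-wise descriptive
statistics with the skewness/kurtosis normality rule.

All derivations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_arterial_pressure",
    "non_hdl",
    "egfr_mdrd",
    "nephropathy",
    "medication_flags",
    "load_atc_table",
    "cohort_description",
    "MED_CLASSES",
]

MED_CLASSES = ["metformin", "su", "insulin", "acei_arb", "statin"]

# micro- and high/macro-albuminuria ACR thresholds by sex (mg/mmol)
_ACR_MICRO = {"male": 2.5, "female": 3.5}
_ACR_HIGH = {"male": 12.5, "female": 17.5}

CREATININE_UMOL_PER_MGDL = 88.4


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (2 x diastolic + systolic) / 3, in mm Hg."""
    if dbp <= 0 or sbp < dbp:
        raise ValueError(f"need sbp >= dbp > 0, got sbp={sbp}, dbp={dbp}")
    return (2.0 * dbp + sbp) / 3.0


def non_hdl(total_chol: float, hdl: float) -> float:
    """Non-HDL cholesterol = total cholesterol - HDL (mmol/L).

    Note: cohort tables sometimes print a measured non-HDL that differs from
    the subtraction in the last digit (rounding of the inputs); this function
    always returns the exact difference.
    """
    if hdl < 0 or hdl > total_chol:
        raise ValueError(f"need total_chol >= hdl >= 0, got {total_chol}, {hdl}")
    return total_chol - hdl


def egfr_mdrd(
    creatinine_umol: float, age: float, sex: str, black: bool = False
) -> float:
    """eGFR (mL/min/1.73 m2) by the 4-variable MDRD study equation.

    IDMS-traceable 175-coefficient version:
    175 x (Scr mg/dL)^-1.154 x age^-0.203 x 0.742 [female] x 1.212 [black].
    Creatinine is taken in umol/L and converted at 88.4 umol/L per mg/dL.
    Ethnicity defaults to non-black when unrecorded.
    """
    if creatinine_umol <= 0:
        raise ValueError("creatinine must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr = creatinine_umol / CREATININE_UMOL_PER_MGDL
    egfr = 175.0 * scr**-1.154 * age**-0.203
    if sex == "female":
        egfr *= 0.742
    if black:
        egfr *= 1.212
    return egfr


def nephropathy(acr_history: Sequence[float], sex: str) -> bool:
    """Diabetic nephropathy from an ACR measurement history.

    True when at least two of the last three consecutive measurements are at
    or above the sex-specific microalbuminuria threshold (2.5 men / 3.5
    women), or any single measurement reaches the high-microalbuminuria /
    macroalbuminuria threshold (12.5 men / 17.5 women).  "Two of three
    consecutive" is read as a sliding window over the final three values.
    """
    acrs = list(acr_history)
    if not acrs:
        raise ValueError("ACR history is empty")
    if any(a < 0 for a in acrs):
        raise ValueError("ACR values must be non-negative")
    micro, high = _ACR_MICRO[sex], _ACR_HIGH[sex]
    if any(a >= high for a in acrs):
        return True
    window = acrs[-3:]
    return sum(a >= micro for a in window) >= 2


def load_atc_table(path: str | Path | None = None) -> pd.DataFrame:
    """ATC-code -> medication-class grouping table (columns: atc_code, class)."""
    p = (
        Path(path)
        if path is not None
        else Path(resources.files("glycomeds") / "data" / "atc_classes.tsv")
    )
    df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    if not {"atc_code", "class"}.issubset(df.columns):
        raise ValueError("ATC table needs columns atc_code, class")
    unknown = set(df["class"]) - set(MED_CLASSES)
    if unknown:
        raise ValueError(f"ATC table maps to unknown classes {sorted(unknown)}")
    return df


def medication_flags(
    atc_codes: Iterable[str], atc_table: pd.DataFrame | None = None
) -> dict[str, bool]:
    """Per-class boolean medication flags from a subject's ATC codes.

    ACE inhibitors and ARBs collapse into the single ``acei_arb`` composite.
    Unknown codes are ignored (logged at debug level).
    """
    import logging

    if atc_table is None:
        atc_table = load_atc_table()
    lookup = dict(zip(atc_table["atc_code"], atc_table["class"]))
    flags = {c: False for c in MED_CLASSES}
    for code in atc_codes:
        cls = lookup.get(code.strip().upper())
        if cls is None:
            logging.getLogger(__name__).debug("unknown ATC code %r ignored", code)
            continue
        flags[cls] = True
    return flags


@dataclass
class VariableComparison:
    variable: str
    kind: str  # continuous | categorical
    test: str  # t-test | wilcoxon | chi2
    summary: dict  # per-group mean(SD) or median(IQR), or contingency counts
    statistic: float
    p_value: float


def _is_normalish(x: np.ndarray) -> bool:
    """Skewness and excess kurtosis both within [-1, 1] (bias-corrected)."""
    skew = stats.skew(x, bias=False)
    kurt = stats.kurtosis(x, fisher=True, bias=False)
    return abs(skew) <= 1.0 and abs(kurt) <= 1.0


def cohort_description(
    table: pd.DataFrame,
    group: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> list[VariableComparison]:
    """Two-group descriptive comparison of clinical variables.

    Continuous variables use Student's t-test when both groups pass the
    skewness/kurtosis normality rule (both within [-1, +1]) and are then
    summarised as mean (SD); otherwise the Wilcoxon rank-sum test and
    median (IQR).  Categorical variables use the chi-square test on the
    contingency table.
    """
    levels = table[group].dropna().unique()
    if len(levels) != 2:
        raise ValueError(f"grouping column {group!r} must have exactly 2 levels")
    g0 = table[table[group] == levels[0]]
    g1 = table[table[group] == levels[1]]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs at least 3 subjects")

    out: list[VariableComparison] = []
    for var in continuous:
        a = g0[var].dropna().to_numpy(dtype=float)
        b = g1[var].dropna().to_numpy(dtype=float)
        if _is_normalish(a) and _is_normalish(b):
            stat, p = stats.ttest_ind(a, b)
            summ = {
                str(levels[0]): f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                str(levels[1]): f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
            }
            test = "t-test"
        else:
            stat, p = stats.ranksums(a, b)
            iqr = lambda x: np.percentile(x, 75) - np.percentile(x, 25)
            summ = {
                str(levels[0]): f"{np.median(a):.2f} ({iqr(a):.2f})",
                str(levels[1]): f"{np.median(b):.2f} ({iqr(b):.2f})",
            }
            test = "wilcoxon"
        out.append(
            VariableComparison(var, "continuous", test, summ, float(stat), float(p))
        )
    for var in categorical:
        ct = pd.crosstab(table[group], table[var])
        stat, p, _, _ = stats.chi2_contingency(ct, correction=False)
        out.append(
            VariableComparison(
                var,
                "categorical",
                "chi2",
                {"table": ct.to_dict()},
                float(stat),
                float(p),
            )
        )
    return out
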