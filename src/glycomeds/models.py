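"""Per-cohort association models: trait ~ medication + covariates.

Linear models regress each standardized derived trait on a medication-use
indicator plus the covariate set of the chosen model variant, so betas are
differences in SD units between users and non-users at fixed covariates.
A logistic variant models case/control status on a trait.  Model variants
follow the study recipe:

* basic: age, sex and their interaction;
* full: basic + BMI, HDL, non-HDL, CVD, diabetes duration and eGFR, plus
  per-medication extras (HbA1c for the glucose-lowering drugs; nephropathy
  and MAP for ACE inhibitors/ARBs; former/current smoking for statins);
* full+comed: full + the other medication-class indicators;
* full+interaction: full + co-medication + metformin x statin;
* subgroup: full, fitted on subjects using at most the index medication
  among metformin, ACE inhibitor/ARB and statin.

Missing data are handled by complete-case analysis per model, with an
exclusion report so model-specific n is visible.  Age is mean-centered
within cohort (sex coded female=0, male=1) before the age x sex product is
formed, which stabilizes the main effects; the medication beta is invariant
to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clinical import MED_CLASSES

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "ModelError",
    "build_model_spec",
    "complete_case_filter",
    "design_matrix",
    "fit_linear",
    "fit_linear_many",
    "fit_logistic",
    "CASE_CONTROL_COVARIATES",
]

VARIANTS = ["basic", "full", "full+comed", "full+interaction", "subgroup"]

_FULL_BASE = ["age", "sex", "age:sex", "bmi", "hdl", "non_hdl", "cvd", "duration", "egfr"]
_EXTRA = {
    "metformin": ["hba1c"],
    "su": ["hba1c"],
    "insulin": ["hba1c"],
    "acei_arb": ["nephropathy", "map"],
    "statin": ["smoking_former", "smoking_current"],
}
CASE_CONTROL_COVARIATES = [
    "age",
    "sex",
    "age:sex",
    "bmi",
    "hdl",
    "non_hdl",
    "smoking_former",
    "smoking_current",
]


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    name: str
    medication: str
    covariates: tuple[str, ...]
    subgroup_filter: Callable[[pd.DataFrame], pd.Series] | None = None

    @property
    def columns_needed(self) -> list[str]:
        """Raw table columns this spec reads (interaction/dummy terms resolved)."""
        cols = {self.medication}
        for term in self.covariates:
            if term == "age:sex" or term == "metformin:statin":
                cols.update(term.split(":"))
            elif term in ("smoking_former", "smoking_current"):
                cols.add("smoking")
            else:
                cols.add(term)
        return sorted(cols)


def build_model_spec(medication: str, variant: str) -> ModelSpec:
    """The exact covariate list for one medication class and model variant."""
    if medication not in MED_CLASSES:
        raise ModelError(f"unknown medication class {medication!r}")
    if variant not in VARIANTS:
        raise ModelError(f"unknown model variant {variant!r}")

    if variant == "basic":
        terms = ["age", "sex", "age:sex"]
        return ModelSpec("basic", medication, tuple(terms))

    terms = _FULL_BASE + _EXTRA[medication]
    if variant == "full":
        return ModelSpec("full", medication, tuple(terms))

    comeds = [m for m in MED_CLASSES if m != medication]
    if variant == "full+comed":
        return ModelSpec("full+comed", medication, tuple(terms + comeds))
    if variant == "full+interaction":
        extra = comeds + ["metformin:statin"]
        if medication in ("metformin", "statin"):
            extra = [t for t in extra if t != "metformin:statin"] + ["metformin:statin"]
        return ModelSpec("full+interaction", medication, tuple(terms + extra))

    # subgroup: users of at most the index medication among the three
    # co-prescribed classes (metformin, ACE inhibitor/ARB, statin)
    trio = ["metformin", "acei_arb", "statin"]

    def only_index(df: pd.DataFrame) -> pd.Series:
        others = [m for m in trio if m != medication]
        mask = pd.Series(True, index=df.index)
        for o in others:
            mask &= ~df[o].astype(bool)
        return mask

    return ModelSpec("subgroup", medication, tuple(terms), subgroup_filter=only_index)


@dataclass
class AssociationResult:
    cohort: str
    trait: str
    medication: str
    model: str
    beta: float
    se: float
    p_value: float
    n_users: int
    n_nonusers: int
    flag: str = ""  # e.g. "perfect_separation"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def complete_case_filter(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows missing any model column; report missing counts per column."""
    present = [c for c in columns if c in table.columns]
    absent = [c for c in columns if c not in table.columns]
    if absent:
        raise ModelError(f"model terms missing from table: {absent}")
    report = {c: int(table[c].isna().sum()) for c in present}
    kept = table.dropna(subset=present)
    if kept.empty:
        raise ModelError("no complete cases left after filtering")
    return kept, report


def _encode_base_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric copies of columns used by term construction."""
    df = table.copy()
    if df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(float)
    if "smoking" in df.columns:
        df["smoking_former"] = (df["smoking"] == "former").astype(float)
        df["smoking_current"] = (df["smoking"] == "current").astype(float)
    for c in df.columns:
        if df[c].dtype == bool:
            df[c] = df[c].astype(float)
    return df


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix with intercept, medication indicator first, then covariates."""
    df = _encode_base_columns(table)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X[spec.medication] = df[spec.medication].astype(float)
    age_c = df["age"] - df["age"].mean()
    for term in spec.covariates:
        if term == "age":
            X["age"] = age_c
        elif term == "age:sex":
            X["age:sex"] = age_c * df["sex"]
        elif term == "metformin:statin":
            X["metformin:statin"] = df["metformin"].astype(float) * df["statin"].astype(
                float
            )
        else:
            X[term] = df[term].astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ModelError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear terms: {worst}"
        )
    return X


def _counts(med: pd.Series) -> tuple[int, int]:
    users = int(med.astype(bool).sum())
    return users, int(len(med) - users)


def fit_linear(
    trait_values: pd.Series,
    table: pd.DataFrame,
    spec: ModelSpec,
    cohort: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """OLS of one standardized trait on the medication indicator + covariates.

    Returns the medication coefficient with its SE and two-sided t p-value.
    """
    data = table.copy()
    data["__trait__"] = trait_values
    if spec.subgroup_filter is not None:
        data = data[spec.subgroup_filter(data)]
    data, _ = complete_case_filter(data, spec.columns_needed + ["__trait__"])
    X = design_matrix(data, spec)
    if len(data) < X.shape[1] + 2:
        raise ModelError(f"too few complete cases (n={len(data)}) for {X.shape[1]} terms")
    fit = sm.OLS(data["__trait__"].astype(float), X).fit()
    users, nonusers = _counts(data[spec.medication])
    return AssociationResult(
        cohort=cohort,
        trait=trait_name,
        medication=spec.medication,
        model=spec.name,
        beta=float(fit.params[spec.medication]),
        se=float(fit.bse[spec.medication]),
        p_value=float(fit.pvalues[spec.medication]),
        n_users=users,
        n_nonusers=nonusers,
    )


def fit_linear_many(
    trait_matrix: pd.DataFrame,
    table: pd.DataFrame,
    spec: ModelSpec,
    cohort: str = "",
) -> list[AssociationResult]:
    """OLS of many traits sharing one design matrix, in one linear solve.

    Numerically identical to calling :func:`fit_linear` per trait when no
    trait values are missing (the shared complete-case set is the
    intersection); equivalence is exercised in the test suite.  Used by the
    pipeline and the replicate simulation studies, where the per-trait loop
    would dominate runtime.
    """
    from scipy import stats as sps

    data = table.copy()
    if spec.subgroup_filter is not None:
        data = data[spec.subgroup_filter(data)]
    data, _ = complete_case_filter(data, spec.columns_needed)
    tm = trait_matrix.loc[data.index]
    X = design_matrix(data, spec).to_numpy()
    n, p = X.shape
    if n < p + 2:
        raise ModelError(f"too few complete cases (n={n}) for {p} terms")
    med_idx = 1  # medication indicator is always the second design column
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    users, nonusers = _counts(data[spec.medication])

    results = []
    for trait in tm.columns:
        y = tm[trait].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.all():
            beta_all = H @ y
            resid = y - X @ beta_all
            dof = n - p
            sigma2 = resid @ resid / dof
            se = float(np.sqrt(sigma2 * XtX_inv[med_idx, med_idx]))
            beta = float(beta_all[med_idx])
        else:
            if ok.sum() < p + 2:
                results.append(
                    AssociationResult(cohort, trait, spec.medication, spec.name,
                                      np.nan, np.nan, np.nan, users, nonusers,
                                      flag="insufficient_n")
                )
                continue
            Xo = X[ok]
            XtX_inv_o = np.linalg.inv(Xo.T @ Xo)
            beta_all = XtX_inv_o @ Xo.T @ y[ok]
            resid = y[ok] - Xo @ beta_all
            dof = ok.sum() - p
            sigma2 = resid @ resid / dof
            se = float(np.sqrt(sigma2 * XtX_inv_o[med_idx, med_idx]))
            beta = float(beta_all[med_idx])
        tstat = beta / se
        pval = float(2.0 * sps.t.sf(abs(tstat), dof))
        results.append(
            AssociationResult(cohort, trait, spec.medication, spec.name,
                              beta, se, pval, users, nonusers)
        )
    return results


def fit_logistic(
    status: pd.Series,
    trait_values: pd.Series,
    table: pd.DataFrame,
    covariates: list[str] = CASE_CONTROL_COVARIATES,
    cohort: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """Logistic regression of case/control status on one trait + covariates.

    Reports the trait's log-odds coefficient with Wald SE/p.  Perfect
    separation is flagged on the result instead of raising.
    """
    data = table.copy()
    data["__trait__"] = trait_values
    data["__status__"] = status.astype(float)
    cols = sorted(
        {c for t in covariates for c in (t.split(":") if ":" in t else [t])}
        - {"smoking_former", "smoking_current"}
        | ({"smoking"} if any(c.startswith("smoking") for c in covariates) else set())
    )
    data, _ = complete_case_filter(data, cols + ["__trait__", "__status__"])
    if data["__status__"].nunique() < 2:
        raise ModelError("both outcome classes must be present")
    df = _encode_base_columns(data)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["__trait__"] = df["__trait__"].astype(float)
    age_c = df["age"] - df["age"].mean()
    for term in covariates:
        if term == "age":
            X["age"] = age_c
        elif term == "age:sex":
            X["age:sex"] = age_c * df["sex"]
        else:
            X[term] = df[term].astype(float)
    flag = ""
    try:
        import warnings as _w

        with np.errstate(all="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = sm.Logit(df["__status__"], X).fit(
                disp=0, method="newton", tol=1e-10, maxiter=100
            )
        beta = float(fit.params["__trait__"])
        se = float(fit.bse["__trait__"])
        pval = float(fit.pvalues["__trait__"])
        if not fit.mle_retvals.get("converged", True) or not np.isfinite(se) or se > 1e4:
            flag = "perfect_separation"
    except Exception:  # statsmodels raises PerfectSeparationError and friends
        beta, se, pval, flag = np.nan, np.nan, np.nan, "perfect_separation"
    cases = int(df["__status__"].sum())
    return AssociationResult(
        cohort=cohort,
        trait=trait_name,
        medication="case_control",
        model="logistic",
        beta=beta,
        se=se,
        p_value=pval,
        n_users=cases,
        n_nonusers=int(len(df) - cases),
        flag=flag,
    )
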