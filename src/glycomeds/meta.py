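"""Random-effects meta-analysis across cohorts and FDR control across traits.

Per trait, the two cohorts' standardized betas are pooled with the
DerSimonian-Laird moment estimator: with fixed-effect weights w_i = 1/se_i^2
and beta_FE = sum(w b)/sum(w),

    Q    = sum_i w_i (b_i - beta_FE)^2          (Cochran's Q)
    C    = sum(w) - sum(w^2)/sum(w)
    tau2 = max(0, (Q - (k-1)) / C)              (between-study variance)
    w*_i = 1 / (se_i^2 + tau2)
    beta = sum(w* b) / sum(w*),  se = (sum w*)^(-1/2)

with a two-sided normal p-value and I^2 = max(0, (Q-(k-1))/Q).  Across the
trait family of one medication class and model variant, q-values come from
the Benjamini-Hochberg step-up procedure with significance at q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaResult",
    "MetaError",
    "dersimonian_laird",
    "benjamini_hochberg",
    "run_meta_pass",
]


class MetaError(ValueError):
    pass


@dataclass
class MetaResult:
    trait: str
    pooled_beta: float
    pooled_se: float
    p_value: float
    tau2: float
    q_het: float
    i2: float
    k: int
    q_value: float = np.nan
    significant: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def dersimonian_laird(betas, ses, trait: str = "") -> MetaResult:
    """Pool k >= 2 study effects with the DerSimonian-Laird estimator."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    k = b.size
    if k < 2:
        raise MetaError(f"need at least 2 studies, got {k}")
    if (s <= 0).any() or not np.isfinite(s).all() or not np.isfinite(b).all():
        raise MetaError("standard errors must be positive and finite")

    w = 1.0 / s**2
    beta_fe = float((w * b).sum() / w.sum())
    q = float((w * (b - beta_fe) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float((w_star * b).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(
        trait=trait,
        pooled_beta=pooled,
        pooled_se=se,
        p_value=max(p, np.finfo(float).tiny),
        tau2=tau2,
        q_het=q,
        i2=i2,
        k=int(k),
    )


def benjamini_hochberg(p_values, q_cut: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up q-values and significance flags (q <= q_cut).

    q-values are monotone-enforced step-up quantities; flags are invariant
    to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise MetaError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_cut


def run_meta_pass(
    cohort_results: pd.DataFrame,
    q_cut: float = 0.05,
    family: str = "per_medication",
) -> pd.DataFrame:
    """Pool per-cohort association results and apply BH within families.

    ``cohort_results`` is the tidy per-cohort table with columns
    cohort, medication, model, trait, beta, se (one row per fit).  Every
    (medication, model, trait) triple must be present in at least two
    cohorts with identical trait sets, or an error lists the difference.

    ``family`` scopes the BH correction: "per_medication" (default) corrects
    across traits within one (medication, model) family; "global" corrects
    across everything in one pass.
    """
    if family not in ("per_medication", "global"):
        raise MetaError(f"unknown BH family scope {family!r}")
    required = {"cohort", "medication", "model", "trait", "beta", "se"}
    if not required.issubset(cohort_results.columns):
        raise MetaError(f"results table needs columns {sorted(required)}")

    rows = []
    for (med, model), grp in cohort_results.groupby(["medication", "model"], sort=True):
        cohorts = sorted(grp["cohort"].unique())
        if len(cohorts) < 2:
            raise MetaError(
                f"({med}, {model}): need >=2 cohorts, got {cohorts}"
            )
        trait_sets = {c: set(grp.loc[grp["cohort"] == c, "trait"]) for c in cohorts}
        common = set.intersection(*trait_sets.values())
        union = set.union(*trait_sets.values())
        if common != union:
            diff = sorted(union - common)
            raise MetaError(
                f"({med}, {model}): trait sets differ across cohorts; "
                f"not shared: {diff[:10]}"
            )
        for trait in sorted(common):
            sub = grp[grp["trait"] == trait]
            ok = sub["beta"].notna() & sub["se"].notna() & (sub["se"] > 0)
            if ok.sum() < 2:
                continue
            res = dersimonian_laird(sub.loc[ok, "beta"], sub.loc[ok, "se"], trait=trait)
            rows.append({"medication": med, "model": model, **res.as_dict()})
    out = pd.DataFrame(rows)
    if out.empty:
        raise MetaError("no poolable results")

    if family == "per_medication":
        for (_, _), idx in out.groupby(["medication", "model"]).groups.items():
            q, sig = benjamini_hochberg(out.loc[idx, "p_value"], q_cut)
            out.loc[idx, "q_value"] = q
            out.loc[idx, "significant"] = sig
    else:
        q, sig = benjamini_hochberg(out["p_value"], q_cut)
        out["q_value"] = q
        out["significant"] = sig
    out["significant"] = out["significant"].astype(bool)
    return out.sort_values(["medication", "model", "trait"]).reset_index(drop=True)
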