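"""Association model construction and fitting fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycomeds.models import (
    ModelError,
    build_model_spec,
    complete_case_filter,
    design_matrix,
    fit_linear,
    fit_linear_many,
    fit_logistic,
)


def _toy_table(n=200, seed=7):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.normal(65, 10, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(30, 5, n),
            "hdl": rng.normal(1.5, 0.3, n),
            "non_hdl": rng.normal(3.0, 0.9, n),
            "cvd": rng.random(n) < 0.3,
            "duration": rng.gamma(2, 4, n),
            "egfr": rng.normal(80, 20, n),
            "hba1c": rng.normal(52, 11, n),
            "map": rng.normal(99, 11, n),
            "nephropathy": rng.random(n) < 0.2,
            "smoking": rng.choice(["never", "former", "current"], n),
            "metformin": rng.random(n) < 0.5,
            "su": rng.random(n) < 0.3,
            "insulin": rng.random(n) < 0.3,
            "acei_arb": rng.random(n) < 0.5,
            "statin": rng.random(n) < 0.6,
        },
        index=[f"s{i}" for i in range(n)],
    )
    return df


@pytest.mark.parametrize(
    "med, variant, expected_terms",
    [
        ("metformin", "basic", ["age", "sex", "age:sex"]),
        (
            "metformin",
            "full",
            ["age", "sex", "age:sex", "bmi", "hdl", "non_hdl", "cvd", "duration", "egfr", "hba1c"],
        ),
        (
            "statin",
            "full",
            ["age", "sex", "age:sex", "bmi", "hdl", "non_hdl", "cvd", "duration", "egfr",
             "smoking_former", "smoking_current"],
        ),
        (
            "acei_arb",
            "full",
            ["age", "sex", "age:sex", "bmi", "hdl", "non_hdl", "cvd", "duration", "egfr",
             "nephropathy", "map"],
        ),
    ],
)
def test_model_spec_terms(med, variant, expected_terms):
    spec = build_model_spec(med, variant)
    assert list(spec.covariates) == expected_terms


def test_basic_terms_subset_of_full():
    for med in ("metformin", "su", "insulin", "acei_arb", "statin"):
        basic = set(build_model_spec(med, "basic").covariates)
        full = set(build_model_spec(med, "full").covariates)
        assert basic < full


def test_comed_and_interaction_variants():
    spec = build_model_spec("metformin", "full+comed")
    assert {"su", "insulin", "acei_arb", "statin"} <= set(spec.covariates)
    spec = build_model_spec("metformin", "full+interaction")
    assert "metformin:statin" in spec.covariates


def test_subgroup_filter_excludes_co_users():
    spec = build_model_spec("metformin", "subgroup")
    df = _toy_table(100)
    mask = spec.subgroup_filter(df)
    kept = df[mask]
    assert not kept["statin"].any() and not kept["acei_arb"].any()


def test_unknown_variant_rejected():
    with pytest.raises(ModelError):
        build_model_spec("metformin", "no_such_variant")


def test_complete_case_filter_counts():
    df = _toy_table(50)
    df.loc["s3", "hba1c"] = np.nan
    spec_full = build_model_spec("metformin", "full")
    kept, report = complete_case_filter(df, spec_full.columns_needed)
    assert len(kept) == 49 and report["hba1c"] == 1
    # the basic model does not use hba1c, so the row is retained
    spec_basic = build_model_spec("metformin", "basic")
    kept_b, _ = complete_case_filter(df, spec_basic.columns_needed)
    assert len(kept_b) == 50


def test_fit_linear_exact_fit_case():
    """Outcome equal to the medication indicator (after standardization):
    residuals vanish."""
    df = _toy_table(60)
    y = df["metformin"].astype(float)
    y = (y - y.mean()) / y.std(ddof=1)
    spec = build_model_spec("metformin", "basic")
    res = fit_linear(y, df, spec)
    # beta equals the group separation in SD units, and p is tiny
    assert res.p_value < 1e-30
    assert res.n_users + res.n_nonusers == len(df)


def test_fit_linear_matches_normal_equations_oracle():
    """Beta/SE on a small fixture equal the closed-form OLS solution."""
    df = _toy_table(80, seed=11)
    rng = np.random.default_rng(3)
    y = pd.Series(rng.normal(0, 1, len(df)), index=df.index)
    spec = build_model_spec("metformin", "full")
    res = fit_linear(y, df, spec)

    X = design_matrix(df, spec).to_numpy()
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
    resid = y.to_numpy() - X @ beta_hat
    dof = len(df) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    p = 2 * stats.t.sf(abs(beta_hat[1] / se), dof)
    assert res.beta == pytest.approx(beta_hat[1], abs=1e-8)
    assert res.se == pytest.approx(se, abs=1e-8)
    assert res.p_value == pytest.approx(p, abs=1e-8)


def test_fit_linear_many_equals_per_trait_fits():
    df = _toy_table(120, seed=2)
    rng = np.random.default_rng(8)
    tm = pd.DataFrame(
        rng.normal(0, 1, (len(df), 6)), index=df.index, columns=[f"t{i}" for i in range(6)]
    )
    spec = build_model_spec("statin", "full")
    many = {r.trait: r for r in fit_linear_many(tm, df, spec)}
    for t in tm.columns:
        single = fit_linear(tm[t], df, spec, trait_name=t)
        assert many[t].beta == pytest.approx(single.beta, abs=1e-10)
        assert many[t].se == pytest.approx(single.se, abs=1e-10)
        assert many[t].p_value == pytest.approx(single.p_value, abs=1e-10)


def test_orthogonal_covariate_leaves_beta_unchanged():
    """Adding a covariate orthogonal to everything does not move the
    medication beta."""
    n = 128
    rng = np.random.default_rng(0)
    df = _toy_table(n, seed=5)
    y = pd.Series(rng.normal(0, 1, n), index=df.index)
    spec_basic = build_model_spec("metformin", "basic")
    X = design_matrix(df, spec_basic)
    # build a column orthogonal to the design and to y
    q, _ = np.linalg.qr(np.column_stack([X.to_numpy(), y]))
    ortho = rng.normal(0, 1, n)
    ortho -= q @ (q.T @ ortho)
    df2 = df.assign(egfr=ortho)  # reuse a known covariate slot
    spec_plus = build_model_spec("metformin", "basic")
    from dataclasses import replace

    spec_plus = replace(spec_plus, covariates=spec_plus.covariates + ("egfr",))
    r1 = fit_linear(y, df, spec_basic)
    r2 = fit_linear(y, df2, spec_plus)
    assert r2.beta == pytest.approx(r1.beta, abs=1e-10)


def test_fit_linear_row_order_invariant():
    df = _toy_table(90, seed=9)
    y = pd.Series(np.random.default_rng(1).normal(0, 1, len(df)), index=df.index)
    spec = build_model_spec("metformin", "full")
    r1 = fit_linear(y, df, spec)
    perm = np.random.default_rng(2).permutation(df.index)
    r2 = fit_linear(y.loc[perm], df.loc[perm], spec)
    assert r1.beta == pytest.approx(r2.beta, abs=1e-10)
    assert r1.se == pytest.approx(r2.se, abs=1e-10)


def test_rank_deficiency_detected():
    df = _toy_table(60)
    df["non_hdl"] = 2.0 * df["hdl"] + 1.0  # exact collinearity
    df["hdl"] = df["hdl"]
    spec = build_model_spec("metformin", "full")
    df["bmi"] = df["hdl"]  # make it exactly singular
    with pytest.raises(ModelError, match="rank deficient"):
        design_matrix(df, spec)


def test_medication_permutation_gives_uniform_p():
    """Permuting the medication indicator yields approximately uniform
    p-values over repeats."""
    df = _toy_table(150, seed=13)
    rng = np.random.default_rng(99)
    y = pd.Series(rng.normal(0, 1, len(df)), index=df.index)
    spec = build_model_spec("metformin", "basic")
    pvals = []
    for _ in range(500):
        df2 = df.copy()
        df2["metformin"] = rng.permutation(df["metformin"].to_numpy())
        pvals.append(fit_linear(y, df2, spec).p_value)
    # KS test against uniform should not reject wildly
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_logistic_matches_contingency_log_odds():
    """With a binary trait and no covariates beyond the intercept, the
    logistic beta equals the log odds ratio of the 2x2 table."""
    rng = np.random.default_rng(4)
    n = 400
    trait = rng.random(n) < 0.5
    p = np.where(trait, 0.65, 0.45)
    status = rng.random(n) < p
    df = pd.DataFrame({"age": np.zeros(n), "sex": ["male"] * n})
    res = fit_logistic(
        pd.Series(status), pd.Series(trait.astype(float)), df, covariates=[]
    )
    a = ((trait == 1) & status).sum()
    b = ((trait == 1) & ~status).sum()
    c = ((trait == 0) & status).sum()
    d = ((trait == 0) & ~status).sum()
    assert res.beta == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)


def test_logistic_recovers_planted_log_or():
    rng = np.random.default_rng(6)
    n = 2000
    trait = rng.normal(0, 1, n)
    logit = -0.2 + 0.4 * trait
    status = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = pd.DataFrame(
        {
            "age": rng.normal(65, 10, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(30, 5, n),
            "hdl": rng.normal(1.5, 0.3, n),
            "non_hdl": rng.normal(3, 1, n),
            "smoking": rng.choice(["never", "former", "current"], n),
        }
    )
    res = fit_logistic(pd.Series(status), pd.Series(trait), df)
    assert res.beta == pytest.approx(0.4, abs=0.1)


def test_logistic_flags_perfect_separation():
    n = 60
    trait = np.linspace(-2, 2, n)
    status = trait > 0
    df = pd.DataFrame({"age": np.zeros(n), "sex": ["male"] * n})
    res = fit_logistic(pd.Series(status), pd.Series(trait), df, covariates=[])
    assert res.flag == "perfect_separation"
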