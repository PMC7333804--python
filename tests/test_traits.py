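"""Derived-trait registry and computation, against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from glycomeds.glycan import annotate_panel
from glycomeds.traits import (
    RegistryError,
    TraitDefinition,
    compute_trait,
    compute_trait_matrix,
    load_registry,
    selector_matches,
)


def brute_force_trait(tdef, row, annotations):
    """Independent trait oracle: explicit per-analyte loop, no masks/matrices."""
    num = den = 0.0
    any_den = False
    for label, x in row.items():
        ann = annotations[label]
        if not ann.valid:
            continue
        if tdef.weight == "unit":
            w = 1.0
        else:
            feat = {"G": ann.galactoses, "S": ann.sialic_total, "E": ann.E, "L": ann.L}[
                tdef.weight[0]
            ]
            if tdef.weight.endswith("antenna"):
                if ann.antennarity in (None, 0):
                    w = None
                else:
                    w = feat / ann.antennarity
            else:
                if ann.galactoses in (None, 0):
                    w = None
                else:
                    w = feat / ann.galactoses
        if w is None:
            continue
        if selector_matches(tdef.numerator, ann):
            num += w * x
        if selector_matches(tdef.denominator, ann):
            den += x
            any_den = True
    if not any_den or den == 0:
        return float("nan")
    return num / den


def test_registry_has_45_unique_traits(registry):
    assert len(registry) == 45
    assert len({t.name for t in registry}) == 45


def test_registry_contains_every_headline_trait(registry):
    headline = (
        "CA2 CA3 MHy A2F A2EF A2E0F A2LF A2L0F A2S0F A3EF A3LF A3L0F A4F "
        "A2FG A2F0G A2FS0G A2SG A2FSB A2FS0B A2F0S0B A2GS A2FGS A3S A4S "
        "A4FGS A2E A2FGE A3E A4E A4FGE A4F0GE A4FGL A4F0GL A2F0GL A3L A4L "
        "TA2FS0"
    ).split()
    names = {t.name for t in registry}
    assert set(headline) <= names


def test_duplicate_trait_name_rejected(tmp_path):
    bad = tmp_path / "reg.yaml"
    bad.write_text(
        "traits:\n"
        "  - {name: CA2, numerator: {antennarity: 2}, denominator: {class: complex}}\n"
        "  - {name: CA2, numerator: {antennarity: 2}, denominator: {class: complex}}\n"
    )
    with pytest.raises(RegistryError, match="duplicate"):
        load_registry(bad)


def test_unknown_selector_field_rejected():
    with pytest.raises(RegistryError, match="unknown selector"):
        TraitDefinition("X", "", {"no_such_field": 1}, {"class": "complex"})


def test_ca2_toy_panel():
    """CA2 on a 4-analyte toy: complex A2 0.3 of complex mass 0.5 -> 0.6."""
    panel = ["H5N4", "H6N5", "H7N6", "H5N2"]
    anns = annotate_panel(panel)
    row = pd.Series([0.3, 0.1, 0.1, 0.5], index=panel)
    tdef = TraitDefinition(
        "CA2", "", {"class": "complex", "antennarity": 2}, {"class": "complex"}
    )
    assert compute_trait(tdef, row, anns) == pytest.approx(0.3 / 0.5, abs=1e-12)


def test_per_antenna_galactosylation_toy():
    """H5N4 (G2) at 0.5 + H4N4 (G1) at 0.5 -> (0.5*1 + 0.5*0.5) = 0.75."""
    panel = ["H5N4", "H4N4"]
    anns = annotate_panel(panel)
    row = pd.Series([0.5, 0.5], index=panel)
    tdef = TraitDefinition(
        "A2G", "", {"antennarity": 2}, {"antennarity": 2}, weight="G/antenna"
    )
    assert compute_trait(tdef, row, anns) == pytest.approx(0.75, abs=1e-12)


def test_saturated_fucosylation_is_one():
    panel = ["H5N4F1", "H4N4F1E1"]
    anns = annotate_panel(panel)
    row = pd.Series([0.4, 0.6], index=panel)
    tdef = TraitDefinition(
        "A2F", "", {"antennarity": 2, "fucosylated": True}, {"antennarity": 2}
    )
    assert compute_trait(tdef, row, anns) == pytest.approx(1.0, abs=1e-12)


def test_total_denominator_trait_equals_family_abundance(registry, panel68, annotations68, rng):
    x = rng.dirichlet(np.ones(len(panel68)))
    row = pd.Series(x, index=panel68)
    ta2fs0 = next(t for t in registry if t.name == "TA2FS0")
    family = [
        lab
        for lab, a in annotations68.items()
        if a.valid and a.antennarity == 2 and a.fucosylated and a.sialic_total == 0
    ]
    assert compute_trait(ta2fs0, row, annotations68) == pytest.approx(
        row[family].sum(), abs=1e-12
    )


def test_missing_denominator_gives_nan_not_zero(registry, panel68, annotations68):
    row = pd.Series(0.0, index=panel68)
    a2 = [l for l, a in annotations68.items() if a.valid and a.antennarity == 2]
    row[a2] = 1.0 / len(a2)
    tm = compute_trait_matrix(pd.DataFrame([row]), annotations68, registry)
    assert np.isnan(tm["A3L"].iloc[0])  # no triantennary mass anywhere
    assert np.isfinite(tm["A2F"].iloc[0])


def test_trait_matrix_matches_brute_force_oracle(registry, rng):
    """All 45 traits match the independent oracle on 50 random toy panels."""
    from glycomeds.simulate import default_panel

    full = default_panel(68)
    for _ in range(50):
        panel = list(rng.choice(full, size=rng.integers(5, 11), replace=False))
        anns = annotate_panel(panel)
        x = rng.dirichlet(np.ones(len(panel)))
        row = pd.Series(x, index=panel)
        tm = compute_trait_matrix(pd.DataFrame([row]), anns, registry)
        for t in registry:
            expected = brute_force_trait(t, row, anns)
            got = tm[t.name].iloc[0]
            if np.isnan(expected):
                assert np.isnan(got), t.name
            else:
                assert got == pytest.approx(expected, abs=1e-12), t.name


def test_trait_matrix_permutation_invariant(registry, panel68, annotations68, rng):
    x = rng.dirichlet(np.ones(len(panel68)), size=5)
    values = pd.DataFrame(x, columns=panel68)
    perm = list(rng.permutation(panel68))
    tm1 = compute_trait_matrix(values, annotations68, registry)
    tm2 = compute_trait_matrix(values[perm], annotations68, registry)
    pd.testing.assert_frame_equal(tm1, tm2, check_exact=False, rtol=0, atol=1e-15)


def test_complexity_fractions_sum_to_one(registry, panel68, annotations68, rng):
    x = rng.dirichlet(np.ones(len(panel68)), size=20)
    tm = compute_trait_matrix(pd.DataFrame(x, columns=panel68), annotations68, registry)
    ca = tm[["CA1", "CA2", "CA3", "CA4"]].sum(axis=1)
    assert np.allclose(ca, 1.0, atol=1e-12)


def test_unit_traits_in_unit_interval(registry, panel68, annotations68, rng):
    x = rng.dirichlet(np.ones(len(panel68)), size=20)
    tm = compute_trait_matrix(pd.DataFrame(x, columns=panel68), annotations68, registry)
    for t in registry:
        if t.ratio:
            assert (tm[t.name].dropna() >= 0).all()
        else:
            v = tm[t.name].dropna()
            assert ((v >= -1e-12) & (v <= 1 + 1e-12)).all(), t.name


def test_complementary_fucosylation_mixture_identity(panel68, annotations68, rng):
    """Fucosylation within E>=1 and within E==0 average (mass-weighted) to
    fucosylation within all diantennary glycans."""
    x = rng.dirichlet(np.ones(len(panel68)))
    row = pd.Series(x, index=panel68)
    f_all = TraitDefinition("a", "", {"antennarity": 2, "fucosylated": True}, {"antennarity": 2})
    f_e = TraitDefinition(
        "b", "", {"antennarity": 2, "fucosylated": True, "E": "1+"}, {"antennarity": 2, "E": "1+"}
    )
    f_e0 = TraitDefinition(
        "c", "", {"antennarity": 2, "fucosylated": True, "E": 0}, {"antennarity": 2, "E": 0}
    )
    anns = annotations68
    mass = lambda sel: sum(
        row[l] for l, a in anns.items() if selector_matches(sel, a)
    )
    m_e, m_e0 = mass({"antennarity": 2, "E": "1+"}), mass({"antennarity": 2, "E": 0})
    mixture = (
        compute_trait(f_e, row, anns) * m_e + compute_trait(f_e0, row, anns) * m_e0
    ) / (m_e + m_e0)
    assert mixture == pytest.approx(compute_trait(f_all, row, anns), abs=1e-12)


def test_traits_invariant_to_row_rescaling(registry, panel68, annotations68, rng):
    x = rng.dirichlet(np.ones(len(panel68)))
    r1 = pd.Series(x, index=panel68)
    r2 = r1 * 37.5
    for t in registry[:10]:
        a, b = compute_trait(t, r1, annotations68), compute_trait(t, r2, annotations68)
        assert a == pytest.approx(b, abs=1e-12)
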