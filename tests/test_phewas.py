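"""Phecode case/control assignment and the association screen."""

import numpy as np
import pandas as pd
import pytest

import isdi
from isdi.phewas import CASE, CONTROL, EXCLUDED, PhecodeMap, PhewasError


@pytest.fixture()
def mini_map():
    return PhecodeMap(
        pd.DataFrame(
            {
                "phecode": [295.10, 296.20, 250.20, 218.10],
                "label": ["Schizophrenia", "Depression", "Type 2 diabetes", "Uterine leiomyoma"],
                "category": ["Mental disorders", "Mental disorders", "Endocrine / Metabolic", "Genitourinary"],
                "member_codes": ["SYN-295.1", "SYN-296.2", "SYN-250.2", "SYN-218.1"],
                "exclusion_lo": [295, 295, 249, 218],
                "exclusion_hi": [299.99, 299.99, 250.99, 218.99],
                "sex_restriction": [None, None, None, "female"],
            }
        )
    )


@pytest.fixture()
def mini_people():
    return pd.DataFrame(
        {
            "participant_id": range(8),
            "sex": ["male", "female", "female", "male", "female", "male", "female", "male"],
        }
    )


def test_case_control_matrix_hand_checked(mini_map, mini_people):
    events = pd.DataFrame(
        {
            "participant_id": [0, 1, 2, 4, 4, 5, 6],
            "code": ["SYN-295.1", "SYN-296.2", "SYN-250.2", "SYN-295.1", "SYN-250.2", "UNKNOWN-1", "SYN-218.1"],
        }
    )
    status = isdi.build_case_control(events, mini_map, mini_people, min_cases=1)
    C, K, X = CONTROL, CASE, EXCLUDED
    expected = pd.DataFrame(
        {
            # p0 schizophrenia case is excluded-not-control for depression (shared 295-299.99 range)
            "295.1": [K, X, C, C, K, C, C, C],
            "296.2": [X, K, C, C, X, C, C, C],
            "250.2": [C, C, K, C, K, C, C, C],
            # leiomyoma: female-only; all males excluded
            "218.1": [X, C, C, X, C, X, K, X],
        },
        index=pd.Index(range(8), name="participant_id"),
    )
    assert (status[expected.columns] == expected).all().all()
    assert status.attrs["unmapped_codes"] == {"UNKNOWN-1": 1}


def test_min_cases_drops_sparse_phecodes(mini_map, mini_people):
    events = pd.DataFrame({"participant_id": [0], "code": ["SYN-295.1"]})
    status = isdi.build_case_control(events, mini_map, mini_people, min_cases=2)
    assert "295.1" not in status.columns
    assert "295.1" in status.attrs["dropped_phecodes"]


def test_exclusion_range_must_contain_phecode():
    with pytest.raises(PhewasError):
        PhecodeMap(
            pd.DataFrame(
                {
                    "phecode": [300.0],
                    "label": ["x"],
                    "category": ["y"],
                    "member_codes": ["C1"],
                    "exclusion_lo": [301],
                    "exclusion_hi": [302],
                }
            )
        )


def test_toy_map_loads_with_many_categories(toy_map):
    assert len(toy_map.table) >= 30
    assert toy_map.table["category"].nunique() >= 10
    assert toy_map.members("295.10") == ["SYN-295.1"]


def test_bonferroni_threshold_values():
    assert isdi.bonferroni_threshold(1, 0.05) == 0.05
    assert isdi.bonferroni_threshold(10, 0.05) == pytest.approx(0.005)
    printed = float(f"{isdi.bonferroni_threshold(1755, 0.05):.2e}")
    assert printed == 2.85e-5
    with pytest.raises(PhewasError):
        isdi.bonferroni_threshold(0)


def test_logistic_beta_matches_2x2_log_odds_ratio():
    y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
    x = np.r_[np.ones(100), np.zeros(100)]
    rec = isdi.fit_disease_model(y, x)
    assert rec.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
    assert rec.n_cases == 40 and rec.n_controls == 160


def test_degenerate_fits_flagged(rng):
    y = rng.integers(0, 2, 200).astype(float)
    rec = isdi.fit_disease_model(y, np.full(200, 1.3))
    assert not rec.converged and rec.note == "constant exposure"
    rec2 = isdi.fit_disease_model(np.ones(50), rng.standard_normal(50))
    assert not rec2.converged
    sep = isdi.fit_disease_model(np.r_[np.ones(25), np.zeros(25)], np.r_[np.ones(25), np.zeros(25)])
    assert not sep.converged


def test_incremental_r2_null_nesting_and_arithmetic(rng):
    import statsmodels.api as sm

    n = 5000
    age = rng.uniform(20, 80, n)
    x = rng.standard_normal(n)
    y = (rng.random(n) < 0.2).astype(float)
    assert abs(isdi.incremental_r2(y, x, age)) < 1e-3
    assert isdi.incremental_r2(y, x, age) >= -1e-9
    # recompute McFadden deltas from the two fitted log-likelihoods
    X_full = sm.add_constant(np.column_stack([x, age]))
    X_base = sm.add_constant(age)
    full = sm.Logit(y, X_full).fit(disp=False)
    base = sm.Logit(y, X_base).fit(disp=False)
    by_hand = (1 - full.llf / full.llnull) - (1 - base.llf / base.llnull)
    assert isdi.incremental_r2(y, x, age) == pytest.approx(by_hand, abs=1e-10)


def test_significance_uses_strict_inequality(rng):
    n = 2000
    x = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))).astype(float)
    pheno = pd.DataFrame({"42.0": y.astype(int)})
    first = isdi.run_screen(pheno, x, with_incremental_r2=False)
    p = first["p"].iloc[0]
    again = isdi.run_screen(pheno, x, alpha=p, with_incremental_r2=False)
    assert not again["significant"].iloc[0]  # threshold == p is not < p


def test_screen_recovers_effect_directions(small_cohort, completed_small):
    best, _ = completed_small
    scores, _, _ = isdi.derive_isdi(best)
    pmap = isdi.load_toy_map()
    pheno = isdi.build_case_control(small_cohort.events, pmap, small_cohort.participants, min_cases=20)
    rec = isdi.run_screen(
        pheno,
        scores["isdi"],
        small_cohort.participants["age"],
        small_cohort.participants["sex"],
        pmap=pmap,
    )
    rec = rec.set_index("phecode")
    assert rec.loc["295.1", "beta"] > 0 and rec.loc["295.1", "significant"]
    # the negative-effect condition is rarer; the screen must still recover
    # the sign even where power is limited
    assert rec.loc["172.1", "beta"] < 0 and rec.loc["172.1", "p"] < 0.05
    assert (rec["incremental_r2"].dropna() >= -1e-9).all()
    dropped = pheno.attrs["dropped_phecodes"]
    assert dropped and set(dropped).isdisjoint(rec.index)


def test_sex_restricted_phecode_fitted_within_restricted_sex(small_cohort, completed_small):
    best, _ = completed_small
    scores, _, _ = isdi.derive_isdi(best)
    pmap = isdi.load_toy_map()
    pheno = isdi.build_case_control(small_cohort.events, pmap, small_cohort.participants, min_cases=10)
    rec = isdi.run_screen(
        pheno, scores["isdi"], small_cohort.participants["age"], small_cohort.participants["sex"], pmap=pmap
    ).set_index("phecode")
    n_female = (small_cohort.participants["sex"] == "female").sum()
    if "218.1" in rec.index:
        assert rec.loc["218.1", "n_cases"] + rec.loc["218.1", "n_controls"] <= n_female


def test_empty_phenotype_matrix_yields_empty_result():
    out = isdi.run_screen(pd.DataFrame(index=range(5)), np.zeros(5))
    assert out.empty and out.attrs["n_tests"] == 0


def test_categorize_percentages_and_totals():
    rec = pd.DataFrame(
        {
            "category": ["Mental disorders"] * 54 + ["Neoplasms"] * 10,
            "beta": [1.0] * 52 + [-1.0] * 2 + [-1.0] * 10,
            "significant": [True] * 64,
        }
    )
    out = isdi.categorize_results(rec).set_index("category")
    assert out.loc["Mental disorders", "positive"] == 52
    assert out.loc["Mental disorders", "pct_positive"] == 96.3
    assert out.loc["Total", "positive"] == 52 and out.loc["Total", "negative"] == 12
    empty = isdi.categorize_results(rec.assign(significant=False))
    assert empty.empty


def test_compare_exposures_identity_and_hand_computed_t():
    a = pd.DataFrame({"phecode": ["1", "2", "3"], "incremental_r2": [0.01, 0.02, 0.03]})
    b = pd.DataFrame({"phecode": ["1", "2", "3"], "incremental_r2": [0.005, 0.01, 0.02]})
    same = isdi.compare_exposures(a, a.copy())
    assert same["t"] == 0 and same["n_ties"] == 3
    comp = isdi.compare_exposures(a, b)
    # paired t by hand: d = (.005, .01, .01), t = mean(d)/(sd(d)/sqrt(3)) = 5
    assert comp["t"] == pytest.approx(5.0, abs=1e-9)
    assert comp["n_a_above"] == 3
    with pytest.raises(PhewasError):
        isdi.compare_exposures(a, b.iloc[:2])
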