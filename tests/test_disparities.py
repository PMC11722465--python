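"""Disparity identification, attenuation, variance components, mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import isdi
from isdi.disparities import DisparitiesError
from isdi.synthetic_cohort import CohortSpec, DiseaseSpec
from ._oracles import anova_by_hand


def _disparity_cohort(n=5000, seed=13):
    spec = CohortSpec(
        n_participants=n,
        seed=seed,
        missing_rate=0.0,
        disease_specs=[
            DiseaseSpec("direct_pos", "SYN-401.1", -2.0, 0.0, {"Black": 0.8}),
            DiseaseSpec("direct_neg", "SYN-172.1", -1.5, 0.0, {"Black": -0.8}),
        ],
    )
    cohort = isdi.generate_cohort(spec)
    pmap = isdi.load_toy_map()
    pheno = isdi.build_case_control(cohort.events, pmap, cohort.participants, min_cases=10)
    return cohort, pheno


def test_identify_disparities_sign_and_significance():
    cohort, pheno = _disparity_cohort()
    p = cohort.participants
    found, rec = isdi.identify_disparities(pheno, p["group"], "White", p["age"], p["sex"])
    assert "401.1" in found["Black"]  # positive, significant -> disparity
    assert "172.1" not in found["Black"]  # negative effect is never a disparity
    neg = rec.query("phecode == '172.1' and group == 'Black'").iloc[0]
    assert neg["beta"] < 0 and not neg["disparity"]


def test_identify_requires_reference_group():
    cohort, pheno = _disparity_cohort()
    p = cohort.participants
    with pytest.raises(DisparitiesError):
        isdi.identify_disparities(pheno, p["group"], "Martian", p["age"], p["sex"])


def test_attenuation_zero_effect_exposure_changes_nothing(rng):
    cohort, pheno = _disparity_cohort()
    p = cohort.participants
    noise = rng.standard_normal(len(p))  # exposure unrelated to anything
    att = isdi.attenuation(
        pheno, p["group"], "White", p["age"], p["sex"], noise,
        phecodes=["401.1"], target_groups=["Black"], test="naive",
    )
    row = att.iloc[0]
    assert row["attenuation"] == pytest.approx(
        (row["beta_unadjusted"] - row["beta_adjusted"]) / row["beta_unadjusted"]
    )
    assert abs(row["attenuation"]) < 0.2
    assert not row["significant_decrease"] and not row["significant_increase"]


def test_attenuation_full_mediation_design_approaches_one():
    """When the group effect flows entirely through deprivation, adjusting
    for the true deprivation variable removes (almost) the whole group
    coefficient."""
    spec = CohortSpec(
        n_participants=20_000,
        seed=31,
        missing_rate=0.0,
        disease_specs=[DiseaseSpec("mediated", "SYN-295.1", -3.0, 2.0)],
    )
    cohort = isdi.generate_cohort(spec)
    pmap = isdi.load_toy_map()
    pheno = isdi.build_case_control(cohort.events, pmap, cohort.participants, min_cases=10)
    p = cohort.participants
    att = isdi.attenuation(
        pheno, p["group"], "White", p["age"], p["sex"], p["latent_deprivation"],
        phecodes=["295.1"], target_groups=["Black"], test="naive",
    )
    row = att.iloc[0]
    assert row["beta_unadjusted"] > 0.3
    assert 0.75 < row["attenuation"] < 1.25
    assert abs(row["beta_adjusted"]) < abs(row["beta_unadjusted"])


def test_attenuation_bootstrap_flags_real_decrease():
    spec = CohortSpec(
        n_participants=8000,
        seed=37,
        missing_rate=0.0,
        disease_specs=[DiseaseSpec("mediated", "SYN-295.1", -2.5, 2.5)],
    )
    cohort = isdi.generate_cohort(spec)
    pmap = isdi.load_toy_map()
    pheno = isdi.build_case_control(cohort.events, pmap, cohort.participants, min_cases=10)
    p = cohort.participants
    att = isdi.attenuation(
        pheno, p["group"], "White", p["age"], p["sex"], p["latent_deprivation"],
        phecodes=["295.1"], target_groups=["Black"], test="bootstrap", n_boot=60, seed=5,
    )
    assert att.iloc[0]["significant_decrease"]


def test_anova_matches_brute_force_oracle(rng):
    for _ in range(5):
        k = rng.integers(2, 6)
        sizes = rng.integers(3, 12, size=k)
        y = np.concatenate([rng.normal(rng.normal(0, 1), 1.0, s) for s in sizes])
        g = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
        dec = isdi.anova_decomposition(y, g)
        oracle = anova_by_hand(y, g)
        assert dec.ss_between == pytest.approx(oracle["ss_between"], rel=1e-12)
        assert dec.ss_within == pytest.approx(oracle["ss_within"], rel=1e-12)
        assert dec.f_stat == pytest.approx(oracle["f"], rel=1e-12)
        assert dec.p == pytest.approx(oracle["p"], rel=1e-9)
        f_scipy, p_scipy = stats.f_oneway(*[y[g == lab] for lab in np.unique(g)])
        assert dec.f_stat == pytest.approx(float(f_scipy), rel=1e-10)
        assert dec.ss_between + dec.ss_within == pytest.approx(((y - y.mean()) ** 2).sum())
        assert dec.percent_between + dec.percent_within == pytest.approx(100.0)


def test_anova_balanced_closed_form(rng):
    n = 200
    a = rng.normal(0.0, 1.0, n)
    b = rng.normal(0.8, 1.0, n)
    y = np.r_[a, b]
    g = np.r_[["a"] * n, ["b"] * n]
    dec = isdi.anova_decomposition(y, g, n_convention="mean-group-size")
    # balanced design: n0 = n, VB = (MSB - MSW) / n
    assert dec.n0 == n
    assert dec.vb == pytest.approx(max(0.0, (dec.ms_between - dec.ms_within) / n))
    assert dec.vw == pytest.approx(dec.ms_within)


def test_anova_null_truncates_vb(rng):
    y = rng.normal(0, 1, 3000)
    g = np.repeat(["a", "b", "c"], 1000)
    dec = isdi.anova_decomposition(y, g)
    assert dec.percent_within > 99.0
    assert dec.vb >= 0.0


def test_anova_conventions_and_errors(rng):
    y = rng.normal(0, 1, 90)
    g = np.repeat(["a", "b", "c"], 30)
    n0 = {
        conv: isdi.anova_decomposition(y, g, n_convention=conv).n0
        for conv in ("mean-group-size", "balanced-n0", "n-over-k-minus-1")
    }
    assert n0["mean-group-size"] == pytest.approx(30.0)
    assert n0["balanced-n0"] == pytest.approx(30.0)  # balanced: same as N/k
    assert n0["n-over-k-minus-1"] == pytest.approx(45.0)  # N/(k-1)
    with pytest.raises(DisparitiesError):
        isdi.anova_decomposition(y, np.array(["a"] * 90))
    with pytest.raises(DisparitiesError):
        isdi.anova_decomposition([1.0, 2.0, 3.0], ["a", "a", "b"])
    with pytest.raises(DisparitiesError):
        isdi.anova_decomposition(y, g, n_convention="bogus")


def _mediation_data(rng, n=8000, gamma=0.25, beta_m=0.8, beta_t=0.3, intercept=-1.6):
    t = (rng.random(n) < 0.5).astype(float)
    m = 0.4 + gamma * t + 0.15 * rng.standard_normal(n)
    age = rng.uniform(20, 80, n)
    sex = np.where(rng.random(n) < 0.6, "female", "male")
    y = (rng.random(n) < expit(intercept + beta_m * m + beta_t * t)).astype(float)
    return y, t, m, age, sex


def test_mediation_identity_and_determinism(rng):
    y, t, m, age, sex = _mediation_data(rng)
    rec = isdi.mediate(y, t, m, age, sex, n_sims=300, seed=8)
    assert rec.acme + rec.ade == pytest.approx(rec.total, abs=1e-12)
    rec2 = isdi.mediate(y, t, m, age, sex, n_sims=300, seed=8)
    assert rec2.acme == rec.acme and rec2.total == rec.total


def test_mediation_no_mediation_path(rng):
    y, t, m, age, sex = _mediation_data(rng, beta_m=0.0, beta_t=0.5, intercept=-1.5)
    rec = isdi.mediate(y, t, m, age, sex, n_sims=400, seed=9)
    assert rec.acme_ci[0] <= 0.0 <= rec.acme_ci[1]
    assert rec.prop_ci[0] <= 0.0 <= rec.prop_ci[1]


def test_mediation_full_mediation_design(rng):
    y, t, m, age, sex = _mediation_data(rng, gamma=0.3, beta_m=2.0, beta_t=0.0, intercept=-2.5)
    rec = isdi.mediate(y, t, m, age, sex, n_sims=400, seed=10)
    assert rec.prop_ci[0] <= 1.0 <= rec.prop_ci[1]
    assert rec.ade_ci[0] <= 0.0 <= rec.ade_ci[1]


def test_mediation_recovers_analytic_proportion(rng):
    """Small-effect linear-probability approximation: ACME/total should be
    near gamma*beta_m / (gamma*beta_m + beta_t)."""
    y, t, m, age, sex = _mediation_data(rng, gamma=0.25, beta_m=0.8, beta_t=0.3)
    rec = isdi.mediate(y, t, m, age, sex, n_sims=400, seed=11)
    analytic = 0.25 * 0.8 / (0.25 * 0.8 + 0.3)
    assert rec.prop_ci[0] - 0.05 <= analytic <= rec.prop_ci[1] + 0.05


def test_classification_ranges():
    assert isdi.classify_proportion(-0.47) == "negative"
    assert isdi.classify_proportion(0.0) == "partial"
    assert isdi.classify_proportion(0.43) == "partial"
    assert isdi.classify_proportion(1.0) == "partial"
    assert isdi.classify_proportion(1.67) == "exceeds-total"


def test_concordance_identity_and_degenerate_cases():
    att = pd.DataFrame(
        {"phecode": ["1", "2", "3"], "group": ["Black"] * 3, "attenuation": [0.2, 0.6, 1.1]}
    )
    recs = [
        isdi.MediationRecord(
            phecode=p, group="Black", acme=0, ade=0, total=1, prop_mediated=v,
            acme_ci=(0, 0), ade_ci=(0, 0), total_ci=(1, 1), prop_ci=(v, v),
            classification=isdi.classify_proportion(v), unstable=False, n_sims=1,
        )
        for p, v in zip(["1", "2", "3"], [0.2, 0.6, 1.1])
    ]
    out = isdi.attenuation_mediation_concordance(att, recs)
    assert out["pearson"] == pytest.approx(1.0)
    assert np.isnan(isdi.attenuation_mediation_concordance(att.iloc[:2], recs[:2])["pearson"])
    const = att.assign(attenuation=0.5)
    assert np.isnan(isdi.attenuation_mediation_concordance(const, recs)["pearson"])
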