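"""Group health disparities: identification, attenuation, variance
decomposition and counterfactual mediation.

Disparity conditions are phecodes positively and Bonferroni-significantly
associated with a non-reference group (``Disease ~ SIRE + age + sex``).
Attenuation compares the group coefficient before and after adjusting for
the deprivation index; the share of deprivation-index variation lying
within versus between groups comes from a one-way ANOVA with
method-of-moments variance components; mediation uses quasi-Bayesian
counterfactual simulation (linear mediator model, logistic outcome model)
reporting ACME, ADE and total effect on the probability scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .phewas import CASE, EXCLUDED, bonferroni_threshold

logger = logging.getLogger(__name__)


class DisparitiesError(ValueError):
    pass


def _sex_indicator(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        return (arr == "female").astype(float)
    return arr.astype(float)


def _group_design(group, reference: str, age, sex) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded SIRE design with age + sex covariates."""
    garr = np.asarray(group)
    others = sorted(set(garr) - {reference})
    cols = [(garr == g).astype(float) for g in others]
    cols.append(np.asarray(age, float))
    cols.append(_sex_indicator(sex))
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    return X, others


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=False, maxiter=100)
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
        raise RuntimeError("logistic fit did not converge")
    return res


def identify_disparities(
    pheno: pd.DataFrame,
    group,
    reference: str,
    age,
    sex,
    alpha: float = 0.05,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Phecodes positively and Bonferroni-significantly associated with each
    non-reference group.  Returns ({group: [phecode, ...]}, full record table)."""
    garr = np.asarray(group)
    if reference not in set(garr):
        raise DisparitiesError(f"reference group {reference!r} absent")
    rows = []
    for ph in pheno.columns:
        col = pheno[ph].to_numpy()
        keep = col != EXCLUDED
        X, others = _group_design(garr[keep], reference, np.asarray(age, float)[keep], np.asarray(sex)[keep])
        y = (col[keep] == CASE).astype(float)
        for gi, g in enumerate(others):
            if (y[garr[keep] == g] == 1).sum() == 0:
                logger.warning("phecode %s: no cases in group %s; skipped", ph, g)
                rows.append({"phecode": str(ph), "group": g, "beta": np.nan, "p": np.nan, "converged": False})
        try:
            res = _fit_logit(y, X)
        except Exception as exc:
            logger.warning("phecode %s: %s", ph, exc)
            for g in others:
                rows.append({"phecode": str(ph), "group": g, "beta": np.nan, "p": np.nan, "converged": False})
            continue
        for gi, g in enumerate(others):
            if any(r["phecode"] == str(ph) and r["group"] == g for r in rows):
                continue
            beta = float(res.params[1 + gi])
            se = float(res.bse[1 + gi])
            z = beta / se
            rows.append(
                {
                    "phecode": str(ph),
                    "group": g,
                    "beta": beta,
                    "se": se,
                    "p": float(2.0 * stats.norm.sf(abs(z))),
                    "converged": True,
                }
            )
    rec = pd.DataFrame(rows)
    n_tests = int(rec.groupby("group")["converged"].sum().max()) if len(rec) else 1
    threshold = bonferroni_threshold(max(n_tests, 1), alpha)
    rec["disparity"] = rec["converged"] & (rec["beta"] > 0) & (rec["p"] < threshold)
    rec.attrs["threshold"] = threshold
    out = {
        g: sub.loc[sub["disparity"], "phecode"].tolist()
        for g, sub in rec.groupby("group")
    }
    return out, rec


@dataclass
class DisparityRecord:
    phecode: str
    group: str
    beta_unadjusted: float
    se_unadjusted: float
    beta_adjusted: float
    se_adjusted: float
    attenuation: float | None
    diff_p: float
    significant_decrease: bool = False
    significant_increase: bool = False


def attenuation(
    pheno: pd.DataFrame,
    group,
    reference: str,
    age,
    sex,
    exposure,
    phecodes: list[str] | None = None,
    target_groups: list[str] | None = None,
    alpha: float = 0.05,
    test: str = "bootstrap",
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Attenuation of group coefficients by the deprivation index.

    Fits ``Disease ~ SIRE + age + sex`` (unadjusted) and ``Disease ~ SIRE +
    exposure + age + sex`` (adjusted) per phecode, computes the attenuation
    proportion (beta_u - beta_a) / beta_u, and tests the coefficient
    difference: by default a participant-level bootstrap refitting both
    models per resample (the two estimates share the data and are strongly
    dependent), or a naive independent-SE z test (``test="naive"``).
    Difference p-values are Bonferroni-corrected over the phecodes tested.
    """
    if test not in ("bootstrap", "naive"):
        raise DisparitiesError(f"unknown test: {test}")
    garr = np.asarray(group)
    age_arr = np.asarray(age, float)
    sex_arr = np.asarray(sex)
    exp_arr = np.asarray(exposure, float)
    phecodes = [str(p) for p in (phecodes if phecodes is not None else pheno.columns)]
    rng = np.random.default_rng(seed)
    rows = []
    for ph in phecodes:
        col = pheno[ph].to_numpy()
        keep = col != EXCLUDED
        y = (col[keep] == CASE).astype(float)
        Xu, others = _group_design(garr[keep], reference, age_arr[keep], sex_arr[keep])
        Xa = np.insert(Xu, 1 + len(others), exp_arr[keep], axis=1)
        wanted = [g for g in others if target_groups is None or g in target_groups]
        try:
            res_u = _fit_logit(y, Xu)
            res_a = _fit_logit(y, Xa)
        except Exception as exc:
            logger.warning("attenuation: phecode %s failed (%s)", ph, exc)
            continue
        boot_diffs = None
        if test == "bootstrap":
            n = len(y)
            boot_diffs = {g: [] for g in wanted}
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                try:
                    bu = _fit_logit(y[idx], Xu[idx])
                    ba = _fit_logit(y[idx], Xa[idx])
                except Exception:
                    continue
                for gi, g in enumerate(others):
                    if g in boot_diffs:
                        boot_diffs[g].append(bu.params[1 + gi] - ba.params[1 + gi])
        for gi, g in enumerate(others):
            if g not in wanted:
                continue
            bu, su = float(res_u.params[1 + gi]), float(res_u.bse[1 + gi])
            ba, sa = float(res_a.params[1 + gi]), float(res_a.bse[1 + gi])
            diff = bu - ba
            if test == "bootstrap":
                draws = np.asarray(boot_diffs[g])
                se_diff = draws.std(ddof=1) if len(draws) > 1 else np.nan
            else:
                se_diff = np.sqrt(su**2 + sa**2)
            z = diff / se_diff if se_diff and np.isfinite(se_diff) and se_diff > 0 else np.nan
            p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            att = diff / bu if bu != 0 else None
            if att is None:
                logger.warning("attenuation undefined for %s/%s (beta_unadjusted = 0)", ph, g)
            rows.append(
                DisparityRecord(
                    phecode=ph, group=g,
                    beta_unadjusted=bu, se_unadjusted=su,
                    beta_adjusted=ba, se_adjusted=sa,
                    attenuation=att, diff_p=p,
                )
            )
    df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        return df
    threshold = bonferroni_threshold(max(df["phecode"].nunique(), 1), alpha)
    sig = df["diff_p"] < threshold
    df["significant_decrease"] = sig & (df["beta_unadjusted"] > df["beta_adjusted"])
    df["significant_increase"] = sig & (df["beta_unadjusted"] < df["beta_adjusted"])
    df.attrs["threshold"] = threshold
    return df


@dataclass
class VarianceDecomposition:
    f_stat: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    vw: float
    vb: float
    percent_within: float
    percent_between: float
    n_convention: str
    n0: float


def variance_components_from_sums(
    ss_between: float,
    df_between: int,
    ss_within: float,
    df_within: int,
    n0: float,
) -> dict:
    """Method-of-moments components from an ANOVA table's sums of squares.

    VW = MS_within; VB = (MS_between - MS_within) / n0, truncated at 0;
    percentages on VW + VB.  Useful for recomputing a published ANOVA table
    under a chosen divisor convention.
    """
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    vw = ms_w
    vb = max(0.0, (ms_b - ms_w) / n0)
    total = vw + vb
    return {
        "ms_between": ms_b,
        "ms_within": ms_w,
        "vw": vw,
        "vb": vb,
        "percent_within": 100.0 * vw / total,
        "percent_between": 100.0 * vb / total,
    }


def anova_decomposition(
    values, groups, n_convention: str = "mean-group-size"
) -> VarianceDecomposition:
    """One-way ANOVA with method-of-moments variance components.

    Equates mean squares to their expectations: EMS_within = VW and
    EMS_between = n0 * VB + VW, so VW = MS_within and VB = (MS_between -
    MS_within) / n0, truncated at zero.  The divisor ``n0`` is
    configurable: ``"mean-group-size"`` (N/k), ``"balanced-n0"`` (the
    standard unequal-n (N - sum n_i^2/N)/(k-1)), or ``"n-over-k-minus-1"``
    (N/(k-1)).
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise DisparitiesError("need at least 2 groups")
    n_i = np.bincount(inverse)
    if (n_i < 2).any():
        raise DisparitiesError("every group needs at least 2 members")
    N = len(y)
    grand = y.mean()
    means = np.array([y[inverse == i].mean() for i in range(k)])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[inverse]) ** 2))
    df_b, df_w = k - 1, N - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f_stat = ms_b / ms_w
    p = float(stats.f.sf(f_stat, df_b, df_w))
    if n_convention == "mean-group-size":
        n0 = N / k
    elif n_convention == "balanced-n0":
        n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    elif n_convention == "n-over-k-minus-1":
        n0 = N / (k - 1)
    else:
        raise DisparitiesError(f"unknown n_convention: {n_convention}")
    comp = variance_components_from_sums(ss_between, df_b, ss_within, df_w, n0)
    return VarianceDecomposition(
        f_stat=f_stat, p=p, df_between=df_b, df_within=df_w,
        ss_between=ss_between, ss_within=ss_within,
        ms_between=comp["ms_between"], ms_within=comp["ms_within"],
        vw=comp["vw"], vb=comp["vb"],
        percent_within=comp["percent_within"],
        percent_between=comp["percent_between"],
        n_convention=n_convention, n0=float(n0),
    )


@dataclass
class MediationRecord:
    phecode: str
    group: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    prop_ci: tuple[float, float]
    classification: str
    unstable: bool
    n_sims: int
    sims: dict = field(default_factory=dict, repr=False)


def classify_proportion(prop: float) -> str:
    """Three-way mediation classification by proportion mediated."""
    if prop < 0:
        return "negative"
    if prop <= 1:
        return "partial"
    return "exceeds-total"


def mediate(
    y,
    treat,
    mediator,
    age,
    sex,
    n_sims: int = 1000,
    seed: int = 0,
    phecode: str = "",
    group: str = "",
) -> MediationRecord:
    """Quasi-Bayesian counterfactual mediation for a binary outcome.

    Fits ``mediator ~ treat + age + sex`` (OLS) and ``y ~ treat + mediator
    + age + sex`` (logistic), draws coefficient vectors from each model's
    asymptotic sampling distribution, simulates potential outcomes on the
    probability scale, and averages the mediation (ACME), direct (ADE) and
    total effects over draws and the observed covariate distribution.
    Proportion mediated = ACME / total; the record is flagged unstable when
    the total-effect CI covers zero.  Deterministic given ``seed``.
    """
    y = np.asarray(y, float)
    t = np.asarray(treat, float)
    m = np.asarray(mediator, float)
    cov = np.column_stack([np.asarray(age, float), _sex_indicator(sex)])
    n = len(y)
    Xm = sm.add_constant(np.column_stack([t, cov]), has_constant="add")
    ols = sm.OLS(m, Xm).fit()
    sigma = float(np.sqrt(ols.scale))
    Xo = sm.add_constant(np.column_stack([t, m, cov]), has_constant="add")
    logit = _fit_logit(y, Xo)

    rng = np.random.default_rng(seed)
    bm_draws = rng.multivariate_normal(ols.params, ols.cov_params(), size=n_sims)
    bo_draws = rng.multivariate_normal(logit.params, logit.cov_params(), size=n_sims)

    base_m = np.column_stack([np.ones(n), np.zeros(n), cov])  # treat = 0
    d0s = np.empty(n_sims)
    d1s = np.empty(n_sims)
    z0s = np.empty(n_sims)
    z1s = np.empty(n_sims)
    for s in range(n_sims):
        bm = bm_draws[s]
        bo = bo_draws[s]
        eps = rng.normal(0.0, sigma, size=n)
        mu0 = base_m @ bm
        m0 = mu0 + eps
        m1 = mu0 + bm[1] + eps

        def prob(tv: float, mv: np.ndarray) -> np.ndarray:
            return expit(bo[0] + bo[1] * tv + bo[2] * mv + cov @ bo[3:])

        p00, p01 = prob(0.0, m0), prob(0.0, m1)
        p10, p11 = prob(1.0, m0), prob(1.0, m1)
        d0s[s] = np.mean(p01 - p00)
        d1s[s] = np.mean(p11 - p10)
        z0s[s] = np.mean(p10 - p00)
        z1s[s] = np.mean(p11 - p01)

    acme_s = 0.5 * (d0s + d1s)
    ade_s = 0.5 * (z0s + z1s)
    total_s = d1s + z0s
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_s = acme_s / total_s

    def ci(x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    total_ci = ci(total_s)
    unstable = total_ci[0] <= 0.0 <= total_ci[1]
    if unstable:
        logger.warning("mediation %s/%s: total-effect CI covers 0; proportion mediated unstable", phecode, group)
    acme = float(acme_s.mean())
    total = float(total_s.mean())
    prop = acme / total if total != 0 else float("nan")
    return MediationRecord(
        phecode=phecode, group=group,
        acme=acme, ade=float(ade_s.mean()), total=total,
        prop_mediated=prop,
        acme_ci=ci(acme_s), ade_ci=ci(ade_s), total_ci=total_ci, prop_ci=ci(prop_s),
        classification=classify_proportion(prop),
        unstable=unstable, n_sims=n_sims,
        sims={"acme": acme_s, "ade": ade_s, "total": total_s},
    )


def mediate_phecode(
    pheno: pd.DataFrame,
    phecode: str,
    group,
    target: str,
    reference: str,
    mediator,
    age,
    sex,
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationRecord:
    """Mediation for one phecode, one group vs the reference group.

    Restricts to the two groups' non-excluded participants.
    """
    garr = np.asarray(group)
    col = pheno[str(phecode)].to_numpy()
    keep = (col != EXCLUDED) & np.isin(garr, [target, reference])
    return mediate(
        (col[keep] == CASE).astype(float),
        (garr[keep] == target).astype(float),
        np.asarray(mediator, float)[keep],
        np.asarray(age, float)[keep],
        np.asarray(sex)[keep],
        n_sims=n_sims,
        seed=seed,
        phecode=str(phecode),
        group=target,
    )


def attenuation_mediation_concordance(
    attenuation_df: pd.DataFrame, mediation_records: list[MediationRecord]
) -> dict:
    """Correlation of proportion attenuated vs proportion mediated across
    shared (phecode, group) pairs.  Pairs whose mediation record is flagged
    unstable (total-effect CI covering zero: both ratios explode) are
    excluded and counted.  Undefined (NaN) for fewer than 3 usable pairs or
    a zero-variance vector."""
    med = pd.DataFrame(
        [
            {
                "phecode": r.phecode,
                "group": r.group,
                "prop_mediated": r.prop_mediated,
                "unstable": r.unstable,
            }
            for r in mediation_records
        ]
    )
    merged = attenuation_df.merge(med, on=["phecode", "group"], how="inner").dropna(
        subset=["attenuation", "prop_mediated"]
    )
    n_unstable = int(merged["unstable"].sum())
    if n_unstable:
        logger.warning("concordance: excluding %d unstable pair(s)", n_unstable)
    merged = merged[~merged["unstable"]].drop(columns="unstable")
    out = {
        "n": len(merged),
        "n_excluded_unstable": n_unstable,
        "pairs": merged,
        "pearson": float("nan"),
        "spearman": float("nan"),
    }
    if len(merged) < 3:
        logger.warning("concordance undefined: fewer than 3 shared pairs")
        return out
    a = merged["attenuation"].to_numpy(float)
    b = merged["prop_mediated"].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        logger.warning("concordance undefined: zero variance")
        return out
    out["pearson"] = float(stats.pearsonr(a, b).statistic)
    out["spearman"] = float(stats.spearmanr(a, b).statistic)
    return out
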