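"""Seedable synthetic cohort with survey, demographic, area and EHR-style data.

The generator emulates the statistical structure the deprivation-index
pipeline assumes: a latent deprivation factor with group-specific means,
five ordinal survey items produced by thresholding noisy loadings on that
factor, an area-level deprivation index built from area means of the
latent factor, and binary disease outcomes drawn from logistic models on
deprivation, group, age and sex.  The stored ``latent_deprivation`` column
is simulation truth for recovery tests only; no analysis stage reads it.

Default parameters are a frozen pilot calibration against the published
cohort structure: group latent means/sds (Asian 0.24/0.19, Black
0.55/0.22, Hispanic 0.52/0.22, White 0.29/0.22), pairwise item Spearman
correlations inside [0.15, 0.65], a first principal component share near
two-thirds, and an individual-vs-area index correlation near 0.28.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .survey_coding import DEFAULT_RESPONSE_ORDER, ITEMS


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


def _thresholds_from_marginals(probs: list[float]) -> list[float]:
    """Standard-normal cutpoints realizing the given level marginals."""
    cum = np.cumsum(probs)[:-1]
    return [float(v) for v in stats.norm.ppf(cum)]


@dataclass
class ItemSpec:
    """Generative model for one ordinal survey item.

    The item's continuous propensity is ``loading * z + noise`` where ``z``
    is the standardized latent deprivation; ``thresholds`` (strictly
    increasing, length ``n_levels - 1``) cut the propensity into ranks.
    """

    name: str
    n_levels: int
    loading: float
    noise_sd: float
    thresholds: list[float]

    def validate(self) -> None:
        if self.n_levels < 2:
            raise CohortSpecError(f"item {self.name}: n_levels must be >= 2")
        if len(self.thresholds) != self.n_levels - 1:
            raise CohortSpecError(f"item {self.name}: need {self.n_levels - 1} thresholds")
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise CohortSpecError(f"item {self.name}: thresholds not strictly increasing")
        if self.noise_sd < 0:
            raise CohortSpecError(f"item {self.name}: negative noise_sd")


@dataclass
class DiseaseSpec:
    """Logistic outcome model for one synthetic condition.

    log-odds = intercept + beta_deprivation * latent + group_effects[group]
    + beta_age * (age - 50)/10 + beta_sex * 1[female].  Cases emit one
    diagnosis event with ``diagnosis_code``.
    """

    name: str
    diagnosis_code: str
    intercept: float
    beta_deprivation: float
    group_effects: dict[str, float] = field(default_factory=dict)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    sex_restriction: str | None = None  # "female" / "male" / None

    def log_odds(self, latent, group, age, sex) -> np.ndarray:
        eta = (
            self.intercept
            + self.beta_deprivation * np.asarray(latent, float)
            + self.beta_age * (np.asarray(age, float) - 50.0) / 10.0
            + self.beta_sex * (np.asarray(sex) == "female")
        )
        for g, effect in self.group_effects.items():
            eta = eta + effect * (np.asarray(group) == g)
        return eta


# calibrated default marginals, deprivation-increasing rank order
_DEFAULT_MARGINALS = {
    "education": [0.32, 0.27, 0.20, 0.16, 0.04, 0.01],
    "employment": [0.45, 0.12, 0.15, 0.13, 0.15],
    "insurance": [0.90, 0.10],
    "housing": [0.58, 0.35, 0.07],
    "income": [0.05, 0.08, 0.13, 0.15, 0.15, 0.14, 0.12, 0.10, 0.08],
}
_DEFAULT_LOADINGS = {
    "education": 0.78,
    "employment": 0.70,
    "insurance": 0.60,
    "housing": 0.84,
    "income": 0.86,
}


def default_item_specs() -> list[ItemSpec]:
    specs = []
    for name in ITEMS:
        a = _DEFAULT_LOADINGS[name]
        probs = _DEFAULT_MARGINALS[name]
        specs.append(
            ItemSpec(
                name=name,
                n_levels=len(probs),
                loading=a,
                noise_sd=float(np.sqrt(1.0 - a * a)),
                thresholds=_thresholds_from_marginals(probs),
            )
        )
    return specs


def default_disease_specs() -> list[DiseaseSpec]:
    """A panel spanning positive, negative and null deprivation effects and
    direct, indirect and mixed group-effect regimes."""
    return [
        DiseaseSpec("schizophrenia", "SYN-295.1", -5.0, 3.0),
        DiseaseSpec("substance_addiction", "SYN-316.0", -4.5, 2.5, {"Black": 0.3}),
        DiseaseSpec("alcoholism", "SYN-317.0", -4.0, 2.0),
        DiseaseSpec(
            "type_2_diabetes", "SYN-250.2", -3.0, 1.5,
            {"Black": 0.5, "Hispanic": 0.55}, beta_age=0.5, beta_sex=-0.1,
        ),
        DiseaseSpec(
            "hypertension", "SYN-401.1", -1.5, 1.0,
            {"Black": 0.6, "Hispanic": 0.3}, beta_age=0.6, beta_sex=-0.2,
        ),
        DiseaseSpec("melanoma", "SYN-172.1", -3.2, -2.5, beta_age=0.5),
        DiseaseSpec("nevus_non_neoplastic", "SYN-216.0", -3.5, -2.0),
        DiseaseSpec(
            "uterine_leiomyoma", "SYN-218.1", -3.0, -0.8,
            {"Black": 0.8, "Hispanic": 0.5}, sex_restriction="female",
        ),
        DiseaseSpec("viral_hepatitis_c", "SYN-070.3", -4.5, 2.8),
        DiseaseSpec("hiv_disease", "SYN-071.0", -5.0, 2.5, {"Black": 0.7}),
        DiseaseSpec("copd", "SYN-496.0", -3.5, 1.8, beta_age=0.6),
        DiseaseSpec("asthma", "SYN-495.0", -2.8, 0.8),
    ]


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic cohort generator."""

    n_participants: int = 20_000
    group_labels: list[str] = field(default_factory=lambda: ["Asian", "Black", "Hispanic", "White"])
    group_proportions: list[float] = field(default_factory=lambda: [0.0265, 0.1984, 0.2009, 0.5742])
    group_latent_means: list[float] = field(default_factory=lambda: [0.24, 0.55, 0.52, 0.29])
    group_latent_sds: list[float] = field(default_factory=lambda: [0.19, 0.22, 0.22, 0.22])
    item_specs: list[ItemSpec] = field(default_factory=default_item_specs)
    missing_rate: float = 0.05
    missing_mode: str = "mcar"  # or "mar": missingness odds rise with income rank
    n_areas: int | None = None  # default: n_participants // 10
    area_noise_sd: float = 0.01
    disease_specs: list[DiseaseSpec] = field(default_factory=default_disease_specs)
    age_range: tuple[float, float] = (18.0, 85.0)
    sex_labels: tuple[str, str] = ("female", "male")
    sex_proportions: list[float] = field(default_factory=lambda: [0.628, 0.372])
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise CohortSpecError("n_participants must be positive")
        for name, weights in (
            ("group_proportions", self.group_proportions),
            ("sex_proportions", self.sex_proportions),
        ):
            w = np.asarray(weights, float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
                raise CohortSpecError(f"{name} must be nonnegative and sum to 1")
        if not (
            len(self.group_labels)
            == len(self.group_proportions)
            == len(self.group_latent_means)
            == len(self.group_latent_sds)
        ):
            raise CohortSpecError("group field lengths disagree")
        if not 0 <= self.missing_rate < 1:
            raise CohortSpecError("missing_rate must be in [0, 1)")
        if self.missing_mode not in ("mcar", "mar"):
            raise CohortSpecError("missing_mode must be 'mcar' or 'mar'")
        n_areas = self.resolved_n_areas
        if n_areas <= 0:
            raise CohortSpecError("n_areas must be positive")
        if n_areas > self.n_participants:
            raise CohortSpecError("n_areas exceeds n_participants")
        for item in self.item_specs:
            item.validate()

    @property
    def resolved_n_areas(self) -> int:
        return self.n_areas if self.n_areas is not None else max(1, self.n_participants // 10)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """Generated cohort: participants, raw survey labels, diagnosis events."""

    participants: pd.DataFrame  # participant_id, age, sex, group, area_code, area_index, latent_deprivation
    survey_raw: pd.DataFrame  # participant_id + five label columns, NaN = missing
    events: pd.DataFrame  # participant_id, code
    spec: CohortSpec

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.survey_raw.to_csv(out / "survey.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.spec.to_yaml(out / "cohort_spec.yaml")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    g_idx = rng.choice(len(spec.group_labels), size=n, p=np.asarray(spec.group_proportions) / np.sum(spec.group_proportions))
    group = np.asarray(spec.group_labels, object)[g_idx]
    age = rng.uniform(*spec.age_range, size=n)
    sex = np.asarray(spec.sex_labels, object)[
        rng.choice(2, size=n, p=np.asarray(spec.sex_proportions) / np.sum(spec.sex_proportions))
    ]
    latent = np.clip(
        rng.normal(np.asarray(spec.group_latent_means)[g_idx], np.asarray(spec.group_latent_sds)[g_idx]),
        0.0,
        1.0,
    )
    z = _standardize(latent)

    # ordinal items by thresholding loading*z + noise
    survey = pd.DataFrame({"participant_id": np.arange(n)})
    ranks = {}
    for item in spec.item_specs:
        s = item.loading * z + item.noise_sd * rng.standard_normal(n)
        rank = np.searchsorted(np.asarray(item.thresholds), s) + 1
        ranks[item.name] = rank
        labels = DEFAULT_RESPONSE_ORDER[item.name]
        if len(labels) != item.n_levels:
            labels = [f"{item.name}_level_{r}" for r in range(1, item.n_levels + 1)]
        survey[item.name] = np.asarray(labels, object)[rank - 1]

    # missingness
    if spec.missing_rate > 0:
        for item in spec.item_specs:
            if spec.missing_mode == "mcar":
                p_miss = np.full(n, spec.missing_rate)
            else:  # MAR: odds of missingness rise with the income rank
                inc = ranks["income"].astype(float)
                shift = 0.25 * (inc - inc.mean())
                base = np.log(spec.missing_rate / (1 - spec.missing_rate))
                p_miss = expit(base + shift)
                p_miss *= spec.missing_rate / p_miss.mean()  # keep the marginal rate
            mask = rng.random(n) < p_miss
            survey.loc[mask, item.name] = np.nan

    participants = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "age": np.round(age, 2),
            "sex": sex,
            "group": group,
            "latent_deprivation": latent,
        }
    )

    # areas + area-level index
    participants["area_code"] = [f"A{k:05d}" for k in rng.integers(0, spec.resolved_n_areas, size=n)]
    participants = generate_area_index(participants, spec, rng)

    # disease outcomes -> one diagnosis event per case
    ev_pid, ev_code = [], []
    for disease in spec.disease_specs:
        eta = disease.log_odds(latent, group, age, sex)
        p = expit(eta)
        if disease.sex_restriction is not None:
            p = np.where(sex == disease.sex_restriction, p, 0.0)
        case = rng.random(n) < p
        ev_pid.extend(np.flatnonzero(case).tolist())
        ev_code.extend([disease.diagnosis_code] * int(case.sum()))
    events = pd.DataFrame({"participant_id": ev_pid, "code": ev_code}).sort_values(
        ["participant_id", "code"], kind="stable", ignore_index=True
    )

    return SyntheticCohort(participants=participants, survey_raw=survey, events=events, spec=spec)


def generate_area_index(
    participants: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Attach ``area_index``: the area's mean latent deprivation plus noise,
    max-min rescaled to [0, 1]; constant when only one area exists (flagged
    via ``attrs['area_index_degenerate']``)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if "area_code" not in participants.columns:
        raise CohortSpecError("areas not assigned")
    out = participants.copy()
    area_mean = out.groupby("area_code")["latent_deprivation"].mean()
    noise = pd.Series(
        rng.normal(0.0, spec.area_noise_sd, size=len(area_mean)), index=area_mean.index
    )
    idx = area_mean + noise
    rng_span = idx.max() - idx.min()
    if rng_span == 0:
        out["area_index"] = 0.5
        out.attrs["area_index_degenerate"] = True
    else:
        out["area_index"] = ((idx - idx.min()) / rng_span).reindex(out["area_code"]).to_numpy()
        out.attrs["area_index_degenerate"] = False
    return out


def expected_prevalence(spec: CohortSpec, cohort: SyntheticCohort) -> pd.DataFrame:
    """Analytic case-probability expectation per disease, averaged over the
    realized covariates, with its binomial standard error."""
    p_df = cohort.participants
    rows = []
    for disease in spec.disease_specs:
        p = expit(
            disease.log_odds(
                p_df["latent_deprivation"], p_df["group"], p_df["age"], p_df["sex"]
            )
        )
        if disease.sex_restriction is not None:
            p = np.where(p_df["sex"] == disease.sex_restriction, p, 0.0)
        n = len(p)
        rows.append(
            {
                "disease": disease.name,
                "code": disease.diagnosis_code,
                "expected_prevalence": float(np.mean(p)),
                "se": float(np.sqrt(np.sum(p * (1 - p))) / n),
            }
        )
    return pd.DataFrame(rows)
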