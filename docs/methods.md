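# Methods

## The index construction

**Ordinal coding.** Each of the five survey items (education, employment,
health insurance, housing, income) is mapped to ranks `1..L`, higher rank
= greater deprivation. Income brackets and education levels have a
canonical order; housing is own < rent < other. Employment and insurance
are genuinely ambiguous, so their order is treated as data-driven: a
candidate order is scored by its Spearman correlation with the income
ordinal (income being the anchor indicator of deprivation), and whole
ordering schemes are scored by the median of the ten pairwise Spearman
correlations, the maximum winning. Ties break to the lexicographically
smallest permutation / first-listed scheme and are logged. The exact
response-to-rank coding is user-supplied configuration (`CodingTable`);
the shipped default uses BRFSS-style response sets for education,
employment, housing and income and the NHANES yes/no insurance item.

**Imputation.** Missing ordinal cells are filled by chained equations:
each incomplete item is regressed on the other four (cumulative-logit
proportional-odds model for items with more than two levels, binary
logistic for two-level items) and missing entries are drawn from the
fitted conditional category probabilities. Draws are from the estimated
category probabilities, not posterior-parameter draws; this is the
simplest faithful choice given that a single completed dataset, not a
pooled estimate, is the product. Initial fill is a draw from each item's
observed empirical marginal; items are visited in ascending-missingness
order; defaults are `m = 5` completed datasets and 20 sweeps. Validation
masks 9–10% of *observed* cells once per call (holdout fractions outside
[0.09, 0.10] are rejected), re-imputes, and scores each completed dataset
by exact-match rate on the held-out cells; the best dataset is selected.
No Rubin's-rules pooling is performed, by design. A component model that
fails to fit (separation, single observed level, non-convergence) falls
back to an empirical-marginal draw for that item-sweep, logged.

**Polychoric PCA.** For every item pair the latent correlation is
estimated by two-step maximum likelihood: thresholds from the
inverse-normal cumulative marginals, then a bounded scalar optimization
of the bivariate-normal contingency-table likelihood over ρ ∈ (−0.999,
0.999) (`xatol = 1e-6`; cell probabilities floored at 1e-12). Two-step
rather than joint ML is the standard, fast choice and matches common
implementations. Optimizer failure falls back to tie-corrected Spearman,
flagged. If the assembled 5×5 matrix is not positive semidefinite it is
repaired by clipping negative eigenvalues at zero and renormalizing to
unit diagonal, with the repair magnitude logged.

**Scores and orientation.** Participant PC1 scores are the
PC1-loading-weighted sums of the cohort-standardized ordinals (mean 0, sd
1 per item). How participant-level scores should be formed from a
polychoric (latent-scale) PCA is underdetermined; this is the
conventional choice and is documented as such. PC1's sign is fixed so its
loadings sum positive, and after max-min scaling to [0, 1] the index is
oriented to correlate positively with the income ordinal. Orientation is
enforced explicitly because a max-min formula of the form
`(max − x)/(max − min)` would map the most-deprived pole to 0, which
contradicts "all-positive loadings, higher value = more deprived"; the
package always resolves to the deprivation-increasing orientation.

## Downstream analyses

**Phenotypes.** Diagnosis codes map to phecodes; any member code makes a
participant a case; a non-case carrying a code whose phecode value falls
inside the exclusion range is excluded (neither case nor control);
everyone else is a control. Sex-restricted phecodes exclude the other sex
and are fitted within the restricted sex with sex dropped from the
covariates (required for identifiability). Phecodes with fewer than
`min_cases` (default 20) cases are dropped and listed; the case-count
rule for which conditions enter a real screen is exposed as
configuration. A bundled toy phecode map (32 fabricated `SYN-*` codes
across the major disease categories, one member code per phecode) is a
synthetic fixture, not a real ICD release.

**Screen.** `Disease ~ exposure + age + sex` by ML logistic regression;
Wald z and two-sided p for the exposure; age enters linearly in years.
Bonferroni threshold is α divided by the number of converged fits, with
strict `p < threshold`. Incremental R² is the McFadden pseudo-R² of the
full model minus the age+sex model (Nagelkerke and Tjur selectable);
exposure comparisons report per-phecode incremental-R² pairs, counts
above/below the unity line, and a paired t test by default (the two
exposures are evaluated on the same disease set; a two-sample variant is
selectable).

**Disparities and attenuation.** Disparity conditions are phecodes with a
positive, Bonferroni-significant group coefficient versus the reference
group in `Disease ~ SIRE + age + sex`. Attenuation compares that
coefficient with its value in `... + iSDI`, as
`(β_unadj − β_adj)/β_unadj`. Because both estimates come from the same
participants, the default coefficient-difference test bootstraps
participants and refits both models per resample (naive independent-SE z
test selectable); p-values are Bonferroni-corrected over phecodes.

**Variance components.** One-way ANOVA of the index on group, with
method-of-moments components: `VW = MS_within`,
`VB = (MS_between − MS_within)/n₀`, truncated at zero. The divisor n₀ is
configurable — `mean-group-size` (N/k, the default), `balanced-n0` (the
standard unequal-n divisor), and `n-over-k-minus-1` (N/(k−1)) — because
published ANOVA tables of this kind are reproducible only under a
specific, sometimes unstated convention; the helper
`variance_components_from_sums` recomputes components directly from
printed SS/df under any divisor.

**Mediation.** Quasi-Bayesian counterfactual simulation: fit
`mediator ~ group + age + sex` (OLS; age and sex assumed as the mediator
model's covariates) and `Disease ~ group + mediator + age + sex`
(logistic); draw coefficient vectors from each model's asymptotic normal
sampling distribution (default 1,000 draws, seeded); simulate mediator
potential values including residual error; average mediation (ACME),
direct (ADE) and total effects on the probability scale over draws and
the observed covariate distribution. ACME + ADE equals the total effect
exactly per draw under this averaging. Proportion mediated = ACME/total,
classified as negative (< 0), partial ([0, 1]) or exceeds-total (> 1);
records whose total-effect CI covers zero are flagged unstable, and the
attenuation-vs-mediation concordance report excludes them (both ratios
explode with arbitrary sign at near-zero totals; in practice concordance
is evaluated over disparity conditions, whose totals are bounded away
from zero). No exposure-mediator interaction and no sequential-ignorability
sensitivity analysis, by design.

## The synthetic cohort generator

The generator is the package's stand-in for restricted survey/EHR data
and defines the conditions under which the pipeline is tested. It draws:

- **Groups** (Asian/Black/Hispanic/White) with proportions 2.65 / 19.84 /
  20.09 / 57.42%; **latent deprivation** per group as Normal(μ_g, σ_g)
  clipped to [0, 1], with (μ, σ) = (0.24, 0.19), (0.55, 0.22),
  (0.52, 0.22), (0.29, 0.22) — the published group index distributions.
- **Items** by thresholding `loading × z + noise` (z the standardized
  latent factor; noise sd `sqrt(1 − loading²)`), with loadings 0.78
  (education, 6 levels), 0.70 (employment, 5), 0.60 (insurance, 2), 0.84
  (housing, 3), 0.86 (income, 9) and thresholds from realistic marginal
  response shares. This pilot-calibrated configuration puts the pairwise
  Spearman correlations inside [0.15, 0.65] and gives a dominant first
  principal component. Two published features are in tension under a
  single-factor generative model: widening the Spearman span toward its
  published floor (~0.17) requires loadings low enough that discretization
  noise pushes index truth-recovery below 0.9. The calibration prioritizes
  truth recovery; the resulting PC1 share (~66–68%) sits above the
  published ~61% because the synthetic items are cleaner than real survey
  responses (no secondary factors, no response artifacts).
- **Missingness** MCAR at 5% per item by default (no rate is published;
  5% is a typical survey item-nonresponse level), with an optional MAR
  mode whose missingness odds rise with the income rank.
- **Areas** of expected size 10 (participants assigned uniformly), with
  `area_index` = area mean latent deprivation + Normal(0, 0.01) noise,
  max-min rescaled. Random assignment at this area size yields an
  individual-vs-area correlation near the published 0.28; areas and noise
  are the tuning knobs.
- **Diseases** from logistic models on latent deprivation, group, age
  (centered at 50, per decade) and sex, one diagnosis code per case. The
  default panel of 12 conditions spans strong positive, weak, and
  negative deprivation effects, direct and indirect group effects, and a
  female-restricted condition.

The stored `latent_deprivation` column is simulation truth for recovery
tests only; no analysis stage reads it. The generator does **not**
emulate: realistic ICD vocabularies or visit timelines, informative
missingness beyond the income-MAR mode, multi-factor survey structure,
geographic semantics beyond opaque area labels, or diagnosis-access bias.
Passing tests therefore demonstrate correctness of the algorithms under a
clean one-factor world, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Index truth-recovery and correlation-structure checks run at n = 20,000
on the complete-data cohort (the index construction is the object under
test; the missing-data path is exercised separately and end to end in the
pipeline tests — chained imputation of 5% MCAR cells costs roughly one
point of truth-recovery correlation, ~0.89 vs ~0.90). Polychoric recovery
uses n = 50,000 with a 4×4 table against a grid-search ML oracle built on
numerically integrated cell probabilities. Screen calibration uses 2,000
null replicates at n = 400 plus a 20-phecode null screen. Mediation and
concordance designs run at n = 6,000 with 300–500 coefficient draws.
The full-scale default imputation settings (m = 5, 20 sweeps) are the defaults and
are exercised at small n; large-n demonstrations use m = 1–2 with ≤ 5
sweeps, which changes runtime, not the algorithm. All stages are
deterministic given the configured seed (child seeds via
`SeedSequence.spawn`).

## Known limitations

- The polychoric model assumes an underlying bivariate normal per item
  pair; heavy tails or skewed latent structure bias ρ̂.
- Percent-match validation rewards imputations that predict the mode, so
  it can prefer less-dispersed completed datasets; it is used for
  selection only, mirroring the single-dataset design.
- The group-coefficient bootstrap refits full logistic models per
  resample and is the dominant cost of the disparities stage at large n.
- Mediation assumes sequential ignorability; with a simulated confounder
  between mediator and outcome the ACME would be biased, and no
  sensitivity analysis is provided.
- `iSDI` group means are compressed relative to the latent group means
  because the max-min normalization is driven by the sample extremes.
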