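"""Chained-equation multiple imputation for ordinal survey items.

Each incomplete item is iteratively regressed on the other four items:
a proportional-odds (cumulative-logit) model for items with more than two
levels and a binary logistic model for two-level items.  Missing entries
are drawn from the fitted conditional category probabilities.  ``m``
completed datasets are produced and scored by a holdout validation that
masks 9-10% of the observed cells, re-imputes them, and counts exact
matches; the completed dataset with the highest percent match is selected
(no pooling across datasets -- one completed table is the product).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel
import statsmodels.api as sm

from .survey_coding import ITEMS

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationConfig:
    """Settings for chained imputation.

    m: number of completed datasets; max_iterations: chained-equation
    sweeps per dataset; holdout_fraction: share of observed cells masked
    during validation (must lie in [0.09, 0.10]).
    """

    m: int = 5
    max_iterations: int = 20
    holdout_fraction: float = 0.095
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ImputationError("m must be >= 1")
        if self.max_iterations < 1:
            raise ImputationError("max_iterations must be >= 1")
        if not 0.09 <= self.holdout_fraction <= 0.10:
            raise ImputationError("holdout_fraction must lie in [0.09, 0.10]")


@dataclass
class CompletedSurveySet:
    """The ``m`` completed tables plus validation scores and the pick."""

    tables: list[pd.DataFrame]
    scores: np.ndarray | None = None
    selected_index: int | None = None
    sweeps_run: int = 0
    logs: list[str] = field(default_factory=list)


def _item_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in ITEMS]


def _fit_and_draw(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    levels: np.ndarray,
    rng: np.random.Generator,
    warm: dict,
    key: str,
    logs: list[str],
) -> np.ndarray:
    """Fit the conditional model for one item and draw imputations.

    Falls back to an empirical-marginal draw when the component model
    cannot be fitted or does not converge.
    """
    marginal = np.array([(y_obs == lv).mean() for lv in levels])

    def fallback(reason: str) -> np.ndarray:
        msg = f"{key}: fallback to empirical-marginal draw ({reason})"
        logs.append(msg)
        logger.warning(msg)
        return rng.choice(levels, size=len(X_mis), p=marginal / marginal.sum())

    if len(levels) < 2:
        return fallback("single observed level")
    try:
        if len(levels) == 2:
            yb = (y_obs == levels[1]).astype(float)
            Xc = sm.add_constant(X_obs, has_constant="add")
            res = sm.GLM(yb, Xc, family=sm.families.Binomial()).fit(maxiter=100)
            if not np.all(np.isfinite(res.params)):
                return fallback("non-finite logistic fit")
            p1 = res.predict(sm.add_constant(X_mis, has_constant="add"))
            draws = np.where(rng.random(len(X_mis)) < p1, levels[1], levels[0])
            return draws
        y_cat = pd.Series(pd.Categorical(y_obs, categories=levels, ordered=True))
        model = OrderedModel(y_cat, X_obs, distr="logit")
        start = warm.get(key)
        if start is not None and len(start) != model.k_params:
            start = None
        res = model.fit(method="lbfgs", maxiter=200, disp=False, start_params=start)
        if not np.all(np.isfinite(res.params)):
            return fallback("non-finite proportional-odds fit")
        warm[key] = res.params
        probs = np.asarray(model.predict(res.params, exog=X_mis))
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        u = rng.random((len(X_mis), 1))
        return levels[(u > cum).sum(axis=1)]
    except Exception as exc:  # non-convergence, separation, singular design
        return fallback(type(exc).__name__)


def chained_impute(table: pd.DataFrame, config: ImputationConfig) -> CompletedSurveySet:
    """Produce ``config.m`` completed tables; deterministic given the seed.

    Initial fill draws from each item's observed empirical marginal; items
    are visited in order of ascending missingness; observed cells are never
    altered.
    """
    config.validate()
    items = _item_columns(table)
    if not items:
        raise ImputationError("no survey item columns found")
    for c in items:
        if table[c].notna().sum() == 0:
            raise ImputationError(f"item {c!r} has no observed values")

    obs_mask = {c: table[c].notna().to_numpy() for c in items}
    levels = {c: np.sort(table[c].dropna().unique().astype(int)) for c in items}
    n_missing = {c: int((~obs_mask[c]).sum()) for c in items}
    visit = sorted((c for c in items if n_missing[c] > 0), key=lambda c: (n_missing[c], c))

    child_seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    logs: list[str] = []
    tables: list[pd.DataFrame] = []
    for k in range(config.m):
        rng = np.random.default_rng(child_seeds[k])
        work = {c: table[c].to_numpy(dtype=float, na_value=np.nan) for c in items}
        # initial fill from empirical marginals
        for c in visit:
            obs = work[c][obs_mask[c]].astype(int)
            marg = np.array([(obs == lv).mean() for lv in levels[c]])
            miss = ~obs_mask[c]
            work[c][miss] = rng.choice(levels[c], size=miss.sum(), p=marg / marg.sum())
        warm: dict = {}
        if visit:
            for sweep in range(config.max_iterations):
                for c in visit:
                    others = [o for o in items if o != c]
                    X = np.column_stack([work[o] for o in others])
                    obs = obs_mask[c]
                    work[c][~obs] = _fit_and_draw(
                        work[c][obs].astype(int),
                        X[obs],
                        X[~obs],
                        levels[c],
                        rng,
                        warm,
                        f"dataset {k} sweep {sweep} item {c}",
                        logs,
                    )
        completed = table.copy()
        for c in items:
            completed[c] = pd.array(work[c].astype(int), dtype="Int64")
        tables.append(completed)
    return CompletedSurveySet(
        tables=tables, sweeps_run=config.max_iterations if visit else 0, logs=logs
    )


def validate_imputation(table: pd.DataFrame, config: ImputationConfig) -> np.ndarray:
    """Percent exact match on a masked holdout, per imputed dataset.

    Masks ``holdout_fraction`` of the observed cells once (completely at
    random), re-imputes the masked table, and scores each completed dataset
    by the fraction of held-out cells recovered exactly.
    """
    config.validate()
    items = _item_columns(table)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x486F6C64)))
    masked = table.copy()
    held: list[tuple[str, np.ndarray, np.ndarray]] = []
    for c in items:
        obs_idx = np.flatnonzero(table[c].notna().to_numpy())
        k = int(round(config.holdout_fraction * len(obs_idx)))
        if k == 0:
            continue
        pick = rng.choice(obs_idx, size=k, replace=False)
        held.append((c, pick, table[c].to_numpy(dtype=float)[pick].astype(int)))
        col = masked[c].copy()
        col.iloc[pick] = pd.NA
        masked[c] = col
    if not held:
        raise ImputationError("holdout is empty; not enough observed cells")
    completed = chained_impute(masked, config)
    scores = []
    for t in completed.tables:
        match = total = 0
        for c, pick, truth in held:
            imput = t[c].to_numpy(dtype=float)[pick].astype(int)
            match += int((imput == truth).sum())
            total += len(truth)
        scores.append(match / total)
    return np.asarray(scores)


def select_best(cset: CompletedSurveySet) -> pd.DataFrame:
    """Return the completed table with the highest percent match.

    Ties are broken by the lowest dataset index and logged.
    """
    if cset.scores is None:
        raise ImputationError("validation scores not present")
    scores = np.asarray(cset.scores)
    best = int(np.argmax(scores))
    if (scores == scores[best]).sum() > 1:
        msg = f"validation tie at {scores[best]:.4f}; selecting dataset {best}"
        cset.logs.append(msg)
        logger.warning(msg)
    cset.selected_index = best
    return cset.tables[best]


def impute_and_select(
    table: pd.DataFrame, config: ImputationConfig
) -> tuple[pd.DataFrame, CompletedSurveySet]:
    """Impute the real missing cells, score the m datasets by holdout
    validation, and return (selected completed table, full set)."""
    cset = chained_impute(table, config)
    if table[_item_columns(table)].isna().to_numpy().any():
        cset.scores = validate_imputation(table, config)
    else:
        cset.scores = np.ones(config.m)  # nothing to impute; any table matches
    best = select_best(cset)
    return best, cset
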