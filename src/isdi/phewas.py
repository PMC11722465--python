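"""Phecode phenotypes and phenome-wide logistic association screens.

Diagnosis codes are grouped into phecodes to define cases; participants
whose only related codes fall in a phecode's exclusion range are excluded
(neither case nor control); everyone else is a control.  Each retained
phecode is modeled as ``Disease ~ exposure + age + sex`` by maximum-
likelihood logistic regression, with Bonferroni control of the family-wise
error and an incremental pseudo-R^2 comparing the exposure model to the
age+sex baseline.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = 1, 0, -1


class PhewasError(ValueError):
    pass


@dataclass
class PhecodeMap:
    """Phecode -> member diagnosis codes, exclusion range, category, sex."""

    table: pd.DataFrame  # phecode,label,category,member_codes,exclusion_lo,exclusion_hi,sex_restriction

    def __post_init__(self) -> None:
        required = {"phecode", "label", "category", "member_codes", "exclusion_lo", "exclusion_hi"}
        missing = required - set(self.table.columns)
        if missing:
            raise PhewasError(f"phecode map missing columns: {sorted(missing)}")
        if self.table.empty:
            raise PhewasError("phecode map is empty")
        if "sex_restriction" not in self.table.columns:
            self.table["sex_restriction"] = np.nan
        for _, row in self.table.iterrows():
            if not row["exclusion_lo"] <= float(row["phecode"]) <= row["exclusion_hi"]:
                raise PhewasError(f"exclusion range of {row['phecode']} does not contain itself")

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls(pd.read_csv(path, dtype={"member_codes": str}))

    @property
    def phecodes(self) -> list[str]:
        return [str(p) for p in self.table["phecode"]]

    def members(self, phecode) -> list[str]:
        match = self.table[self.table["phecode"].astype(float) == float(phecode)]
        if match.empty:
            raise PhewasError(f"unknown phecode: {phecode}")
        row = match.iloc[0]
        return [c.strip() for c in str(row["member_codes"]).split(";") if c.strip()]


def load_toy_map() -> PhecodeMap:
    """The bundled synthetic toy phecode map (fabricated codes, not a real
    ICD release), spanning the major phecode disease categories."""
    path = importlib.resources.files("isdi").joinpath("data/phecodes_synthetic_toy.csv")
    with path.open() as fh:
        return PhecodeMap(pd.read_csv(fh, dtype={"member_codes": str}))


def build_case_control(
    events: pd.DataFrame,
    pmap: PhecodeMap,
    participants: pd.DataFrame,
    min_cases: int = 20,
) -> pd.DataFrame:
    """Participant x phecode status matrix (1 case, 0 control, -1 excluded).

    A participant with any member code of a phecode is a case; a non-case
    whose codes map to a phecode value inside the exclusion range is
    excluded; sex-restricted phecodes exclude the other sex.  Phecodes with
    fewer than ``min_cases`` cases are dropped (listed in
    ``attrs['dropped_phecodes']``); event codes absent from the map are
    counted in ``attrs['unmapped_codes']``.
    """
    pids = participants["participant_id"].to_numpy()
    code_to_phecode: dict[str, float] = {}
    for _, row in pmap.table.iterrows():
        for c in str(row["member_codes"]).split(";"):
            c = c.strip()
            if c:
                code_to_phecode[c] = float(row["phecode"])
    known = events["code"].isin(code_to_phecode)
    unmapped = events.loc[~known, "code"].value_counts().to_dict()
    if unmapped:
        logger.warning("ignoring %d unmapped event codes", sum(unmapped.values()))
    ev = events[known].copy()
    ev["phecode_value"] = ev["code"].map(code_to_phecode)
    carried = ev.groupby("participant_id")["phecode_value"].agg(set)
    carried = carried.reindex(pids).apply(lambda s: s if isinstance(s, set) else set())

    sex = participants.set_index("participant_id")["sex"].reindex(pids) if "sex" in participants.columns else None
    status = pd.DataFrame(CONTROL, index=pids, columns=pmap.phecodes, dtype=int)
    status.index.name = "participant_id"
    carried_arr = carried.to_numpy()
    for _, row in pmap.table.iterrows():
        ph = str(row["phecode"])
        value = float(row["phecode"])
        lo, hi = float(row["exclusion_lo"]), float(row["exclusion_hi"])
        col = np.full(len(pids), CONTROL, dtype=int)
        for i, codes in enumerate(carried_arr):
            if value in codes:
                col[i] = CASE
            elif any(lo <= v <= hi for v in codes):
                col[i] = EXCLUDED
        restriction = row.get("sex_restriction")
        if isinstance(restriction, str) and restriction and sex is not None:
            col[(sex != restriction).to_numpy() & (col != CASE)] = EXCLUDED
        status[ph] = col

    counts = (status == CASE).sum()
    dropped = counts[counts < min_cases].index.tolist()
    status = status.drop(columns=dropped)
    status.attrs["dropped_phecodes"] = dropped
    status.attrs["unmapped_codes"] = unmapped
    return status


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling family-wise error."""
    if n_tests < 1:
        raise PhewasError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class AssociationRecord:
    phecode: str
    exposure: str
    beta: float
    se: float
    z: float
    p: float
    n_cases: int
    n_controls: int
    category: str | None = None
    incremental_r2: float | None = None
    significant: bool | None = None
    converged: bool = True
    note: str | None = None


def _design(exposure, age=None, sex=None) -> np.ndarray:
    cols = [np.asarray(exposure, float)]
    if age is not None:
        cols.append(np.asarray(age, float))
    if sex is not None:
        sexarr = np.asarray(sex)
        if sexarr.dtype.kind in "OUS":
            cols.append((sexarr == "female").astype(float))
        else:
            cols.append(sexarr.astype(float))
    return sm.add_constant(np.column_stack(cols), has_constant="add")


def fit_disease_model(
    y, exposure, age=None, sex=None, phecode: str = "", exposure_name: str = "isdi"
) -> AssociationRecord:
    """ML logistic fit; Wald z and two-sided p for the exposure term."""
    y = np.asarray(y, float)
    n_cases, n_controls = int((y == 1).sum()), int((y == 0).sum())
    rec = AssociationRecord(
        phecode=phecode, exposure=exposure_name, beta=np.nan, se=np.nan, z=np.nan,
        p=np.nan, n_cases=n_cases, n_controls=n_controls,
    )
    if n_cases == 0 or n_controls == 0:
        rec.converged, rec.note = False, "no cases or no controls"
        return rec
    if np.ptp(np.asarray(exposure, float)) == 0:
        rec.converged, rec.note = False, "constant exposure"
        return rec
    X = _design(exposure, age, sex)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=100)
        if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
            raise RuntimeError("non-convergence")
        rec.beta = float(res.params[1])
        rec.se = float(res.bse[1])
        rec.z = rec.beta / rec.se
        rec.p = float(2.0 * stats.norm.sf(abs(rec.z)))
    except Exception as exc:  # perfect separation, singular design, ...
        rec.converged, rec.note = False, type(exc).__name__
        logger.warning("phecode %s: logistic fit failed (%s)", phecode, exc)
    return rec


def _pseudo_r2(res, y: np.ndarray, kind: str) -> float:
    if kind == "mcfadden":
        return 1.0 - res.llf / res.llnull
    if kind == "nagelkerke":
        n = len(y)
        cox = 1.0 - np.exp(2.0 * (res.llnull - res.llf) / n)
        return cox / (1.0 - np.exp(2.0 * res.llnull / n))
    if kind == "tjur":
        p = res.predict()
        return float(p[y == 1].mean() - p[y == 0].mean())
    raise PhewasError(f"unknown pseudo-R2 kind: {kind}")


def incremental_r2(y, exposure, age=None, sex=None, kind: str = "mcfadden") -> float:
    """Pseudo-R^2 of ``y ~ exposure + covariates`` minus that of the
    covariates-only model.  NaN if either nested fit fails."""
    y = np.asarray(y, float)
    X_full = _design(exposure, age, sex)
    X_base = X_full[:, [0] + list(range(2, X_full.shape[1]))]
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=False, maxiter=100)
            base = sm.Logit(y, X_base).fit(disp=False, maxiter=100)
        if not (full.mle_retvals.get("converged") and base.mle_retvals.get("converged")):
            raise RuntimeError("non-convergence")
    except Exception as exc:
        logger.warning("incremental R2 undefined (%s)", exc)
        return float("nan")
    return float(_pseudo_r2(full, y, kind) - _pseudo_r2(base, y, kind))


def run_screen(
    pheno: pd.DataFrame,
    exposure: pd.Series | np.ndarray,
    age=None,
    sex=None,
    pmap: PhecodeMap | None = None,
    alpha: float = 0.05,
    exposure_name: str = "isdi",
    pseudo_r2: str = "mcfadden",
    with_incremental_r2: bool = True,
) -> pd.DataFrame:
    """One association record per phecode column of ``pheno``.

    Excluded participants are dropped per phecode; sex-restricted phecodes
    are fitted within the restricted sex with sex removed from the
    covariates.  Significance is Bonferroni over the number of converged
    fits.  Returns a DataFrame of records (``attrs`` carry the threshold
    and positive/negative significant counts).
    """
    if pheno.shape[1] == 0:
        logger.warning("empty phenotype matrix: nothing to screen")
        out = pd.DataFrame(columns=["phecode", "exposure", "beta", "se", "z", "p"])
        out.attrs.update({"threshold": np.nan, "n_tests": 0, "n_sig_pos": 0, "n_sig_neg": 0})
        return out
    categories = {}
    restrictions = {}
    if pmap is not None:
        categories = dict(zip(pmap.table["phecode"].astype(str), pmap.table["category"]))
        restrictions = dict(zip(pmap.table["phecode"].astype(str), pmap.table["sex_restriction"]))
    exposure = np.asarray(exposure, float)
    age_arr = None if age is None else np.asarray(age, float)
    sex_arr = None if sex is None else np.asarray(sex)
    records = []
    for ph in pheno.columns:
        col = pheno[ph].to_numpy()
        keep = col != EXCLUDED
        restriction = restrictions.get(str(ph))
        sex_for_fit = sex_arr
        if isinstance(restriction, str) and restriction and sex_arr is not None:
            keep &= sex_arr == restriction
            sex_for_fit = None
        y = col[keep]
        rec = fit_disease_model(
            y,
            exposure[keep],
            None if age_arr is None else age_arr[keep],
            None if sex_for_fit is None else sex_for_fit[keep],
            phecode=str(ph),
            exposure_name=exposure_name,
        )
        rec.category = categories.get(str(ph))
        if with_incremental_r2 and rec.converged:
            rec.incremental_r2 = incremental_r2(
                y,
                exposure[keep],
                None if age_arr is None else age_arr[keep],
                None if sex_for_fit is None else sex_for_fit[keep],
                kind=pseudo_r2,
            )
        records.append(rec)
    df = pd.DataFrame([vars(r) for r in records])
    n_tests = int(df["converged"].sum())
    threshold = bonferroni_threshold(max(n_tests, 1), alpha)
    df["significant"] = df["converged"] & (df["p"] < threshold)
    df.attrs["threshold"] = threshold
    df.attrs["n_tests"] = n_tests
    df.attrs["n_sig_pos"] = int((df["significant"] & (df["beta"] > 0)).sum())
    df.attrs["n_sig_neg"] = int((df["significant"] & (df["beta"] < 0)).sum())
    return df


def categorize_results(records: pd.DataFrame) -> pd.DataFrame:
    """Significant positive/negative association counts and row percentages
    per phecode category, with a Total row."""
    sig = records[records["significant"].fillna(False)].copy()
    rows = []
    for cat, sub in sig.groupby("category", dropna=False):
        pos = int((sub["beta"] > 0).sum())
        neg = int((sub["beta"] < 0).sum())
        rows.append({"category": cat, "positive": pos, "negative": neg})
    out = pd.DataFrame(rows, columns=["category", "positive", "negative"])
    if out.empty:
        out = pd.DataFrame(columns=["category", "positive", "negative", "pct_positive", "pct_negative"])
        return out
    out = out.sort_values("category", ignore_index=True)
    total = pd.DataFrame(
        [{"category": "Total", "positive": out["positive"].sum(), "negative": out["negative"].sum()}]
    )
    out = pd.concat([out, total], ignore_index=True)
    denom = (out["positive"] + out["negative"]).replace(0, np.nan)
    out["pct_positive"] = np.round(100.0 * out["positive"] / denom, 1)
    out["pct_negative"] = np.round(100.0 * out["negative"] / denom, 1)
    return out


def compare_exposures(
    records_a: pd.DataFrame, records_b: pd.DataFrame, test: str = "paired"
) -> dict:
    """Compare two exposures' incremental R^2 across the same phecode set.

    Reports per-phecode pairs, counts above/below the unity line, means and
    normal-theory 95% CIs, and a t test for the mean difference (``paired``
    across phecodes by default, ``two-sample`` selectable).
    """
    a = records_a.set_index("phecode")
    b = records_b.set_index("phecode")
    if set(a.index) != set(b.index):
        raise PhewasError("phecode sets differ between exposures")
    b = b.reindex(a.index)
    pairs = pd.DataFrame(
        {
            "phecode": a.index,
            "r2_a": a["incremental_r2"].to_numpy(float),
            "r2_b": b["incremental_r2"].to_numpy(float),
        }
    ).dropna()
    xa, xb = pairs["r2_a"].to_numpy(), pairs["r2_b"].to_numpy()
    diff = xa - xb
    if test == "paired":
        if np.allclose(diff, 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = map(float, stats.ttest_rel(xa, xb)[:2])
    elif test == "two-sample":
        t_stat, p_val = map(float, stats.ttest_ind(xa, xb)[:2])
    else:
        raise PhewasError(f"unknown test: {test}")

    def mean_ci(x: np.ndarray) -> tuple[float, float]:
        half = 1.96 * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        return float(x.mean()), float(half)

    mean_a, half_a = mean_ci(xa)
    mean_b, half_b = mean_ci(xb)
    return {
        "pairs": pairs,
        "n_a_above": int((diff > 0).sum()),
        "n_b_above": int((diff < 0).sum()),
        "n_ties": int((diff == 0).sum()),
        "mean_r2_a": mean_a,
        "ci95_half_a": half_a,
        "mean_r2_b": mean_b,
        "ci95_half_b": half_b,
        "t": t_stat,
        "p": p_val,
        "sig_pos_a": records_a.attrs.get("n_sig_pos"),
        "sig_neg_a": records_a.attrs.get("n_sig_neg"),
        "sig_pos_b": records_b.attrs.get("n_sig_pos"),
        "sig_neg_b": records_b.attrs.get("n_sig_neg"),
    }
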