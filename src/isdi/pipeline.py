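"""End-to-end orchestration: simulate -> encode -> impute -> index ->
screen -> disparities, with CSV intermediates and a reproducibility
manifest.

Every stage reads its inputs from and writes its outputs to a single
output directory, so stages can be rerun standalone on the intermediate
CSVs.  The manifest records, per stage, the files written and their
SHA-256 hashes; reruns with the same configuration produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import survey_coding, imputation, deprivation_index, phewas, disparities as disp
from .synthetic_cohort import CohortSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "encode", "impute", "index", "screen", "disparities", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for the full pipeline; the seed feeds every stage."""

    seed: int = 0
    n_participants: int = 20_000
    imputation_m: int = 5
    imputation_max_iterations: int = 20
    holdout_fraction: float = 0.095
    alpha: float = 0.05
    min_cases: int = 20
    pseudo_r2: str = "mcfadden"
    reference_group: str = "White"
    mediation_n_sims: int = 1000
    attenuation_test: str = "bootstrap"
    n_boot: int = 200
    anova_convention: str = "mean-group-size"
    phecode_map_path: str | None = None  # None -> bundled synthetic toy map

    def validate(self) -> None:
        if self.phecode_map_path is not None and not Path(self.phecode_map_path).exists():
            raise PipelineError("validate", f"phecode map not found: {self.phecode_map_path}")
        imputation.ImputationConfig(
            m=self.imputation_m,
            max_iterations=self.imputation_max_iterations,
            holdout_fraction=self.holdout_fraction,
        ).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def phecode_map(self) -> phewas.PhecodeMap:
        if self.phecode_map_path is None:
            return phewas.load_toy_map()
        return phewas.PhecodeMap.from_csv(self.phecode_map_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def summarize_cohort(participants: pd.DataFrame, scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort characteristics per group: n (%), sex n (%), index mean (sd).

    Empty groups are dropped with a warning; percentages derive from counts.
    """
    df = participants.copy()
    if scores is not None:
        df = df.merge(scores[["participant_id", "isdi"]], on="participant_id", how="left")
    groups = [g for g, sub in df.groupby("group") if len(sub)]
    rows = []
    n_total = len(df)
    for name, sub in [("Full Cohort", df)] + [(g, df[df["group"] == g]) for g in sorted(groups)]:
        if len(sub) == 0:
            logger.warning("group %s is empty; dropped from summary", name)
            continue
        row = {
            "group": name,
            "n": len(sub),
            "pct": round(100.0 * len(sub) / n_total, 2),
            "n_male": int((sub["sex"] == "male").sum()),
            "pct_male": round(100.0 * (sub["sex"] == "male").mean(), 2),
            "n_female": int((sub["sex"] == "female").sum()),
            "pct_female": round(100.0 * (sub["sex"] == "female").mean(), 2),
        }
        if "isdi" in sub.columns:
            row["isdi_mean"] = round(float(sub["isdi"].mean()), 4)
            row["isdi_sd"] = round(float(sub["isdi"].std()), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages: tuple[str, ...] = STAGES,
    cohort_spec: CohortSpec | None = None,
) -> dict:
    """Run the requested stages, writing intermediates and a manifest.

    ``cohort_spec`` overrides the default synthetic-cohort specification
    (its seed is still taken from the pipeline config).  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError("validate", f"unknown stages: {sorted(unknown)}")
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
        logger.info("stage %s done in %.1fs (%d files)", stage, time.time() - t0, len(paths))

    def fail(stage: str, exc: Exception):
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(stage, str(exc)) from exc

    coding = survey_coding.CodingTable()
    pmap = config.phecode_map()

    if "simulate" in stages:
        t0 = time.time()
        try:
            spec = cohort_spec or CohortSpec(n_participants=config.n_participants)
            spec.seed = config.seed
            cohort = generate_cohort(spec)
            cohort.to_csv(out)
            record("simulate", [out / f for f in ("participants.csv", "survey.csv", "events.csv")], t0)
        except Exception as exc:
            fail("simulate", exc)

    if "encode" in stages:
        t0 = time.time()
        try:
            raw = pd.read_csv(out / "survey.csv")
            encoded = survey_coding.encode_responses(raw, coding)
            record("encode", [_write(encoded, out / "survey_ordinal.csv")], t0)
        except Exception as exc:
            fail("encode", exc)

    if "impute" in stages:
        t0 = time.time()
        try:
            table = pd.read_csv(out / "survey_ordinal.csv").astype(
                {c: "Int64" for c in survey_coding.ITEMS}
            )
            iconfig = imputation.ImputationConfig(
                m=config.imputation_m,
                max_iterations=config.imputation_max_iterations,
                holdout_fraction=config.holdout_fraction,
                seed=config.seed + 1,
            )
            best, cset = imputation.impute_and_select(table, iconfig)
            validation = pd.DataFrame(
                {"dataset": range(len(cset.scores)), "percent_match": cset.scores}
            )
            validation["selected"] = validation["dataset"] == cset.selected_index
            record(
                "impute",
                [
                    _write(best, out / "survey_completed.csv"),
                    _write(validation, out / "imputation_validation.csv"),
                ],
                t0,
            )
        except Exception as exc:
            fail("impute", exc)

    if "index" in stages:
        t0 = time.time()
        try:
            completed = pd.read_csv(out / "survey_completed.csv")
            participants = pd.read_csv(out / "participants.csv")
            scores, decomp, poly = deprivation_index.derive_isdi(completed)
            decomp_df = pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(decomp.eigenvalues))],
                    "eigenvalue": decomp.eigenvalues,
                    "percent_variance": decomp.percent_variance,
                }
            )
            loadings = pd.DataFrame({"item": decomp.items, "pc1_loading": decomp.pc1_loadings})
            spearman = survey_coding.spearman_matrix(completed).reset_index(names="item")
            area_r = deprivation_index.compare_with_area_index(
                scores, participants.set_index("participant_id")["area_index"].reindex(scores["participant_id"]).to_numpy()
            )
            comparison = pd.DataFrame([{"pearson_isdi_vs_area_index": area_r}])
            record(
                "index",
                [
                    _write(scores, out / "isdi_scores.csv"),
                    _write(decomp_df, out / "pca_variance.csv"),
                    _write(loadings, out / "pc1_loadings.csv"),
                    _write(poly.matrix.reset_index(names="item"), out / "polychoric_matrix.csv"),
                    _write(spearman, out / "spearman_matrix.csv"),
                    _write(comparison, out / "area_comparison.csv"),
                ],
                t0,
            )
        except Exception as exc:
            fail("index", exc)

    if "screen" in stages:
        t0 = time.time()
        try:
            participants = pd.read_csv(out / "participants.csv")
            scores = pd.read_csv(out / "isdi_scores.csv")
            events = pd.read_csv(out / "events.csv")
            pheno = phewas.build_case_control(events, pmap, participants, min_cases=config.min_cases)
            merged = participants.merge(scores, on="participant_id")
            files = []
            screens = {}
            for name, exposure in (("isdi", merged["isdi"]), ("area_index", merged["area_index"])):
                rec = phewas.run_screen(
                    pheno.reindex(merged["participant_id"]),
                    exposure,
                    merged["age"],
                    merged["sex"],
                    pmap=pmap,
                    alpha=config.alpha,
                    exposure_name=name,
                    pseudo_r2=config.pseudo_r2,
                )
                screens[name] = rec
                files.append(_write(rec.drop(columns=["sims"], errors="ignore"), out / f"screen_{name}.csv"))
                files.append(_write(phewas.categorize_results(rec), out / f"categories_{name}.csv"))
            comp = phewas.compare_exposures(screens["isdi"], screens["area_index"])
            comp_df = pd.DataFrame([{k: v for k, v in comp.items() if not isinstance(v, pd.DataFrame)}])
            files.append(_write(comp_df, out / "exposure_comparison.csv"))
            files.append(_write(comp["pairs"], out / "incremental_r2_pairs.csv"))
            pheno_out = pheno.reset_index()
            files.append(_write(pheno_out, out / "phenotypes.csv"))
            record("screen", files, t0)
        except Exception as exc:
            fail("screen", exc)

    if "disparities" in stages:
        t0 = time.time()
        try:
            participants = pd.read_csv(out / "participants.csv")
            scores = pd.read_csv(out / "isdi_scores.csv")
            pheno = pd.read_csv(out / "phenotypes.csv").set_index("participant_id")
            merged = participants.merge(scores, on="participant_id")
            pheno = pheno.reindex(merged["participant_id"])
            found, disparity_rec = disp.identify_disparities(
                pheno, merged["group"], config.reference_group, merged["age"], merged["sex"], alpha=config.alpha
            )
            files = [_write(disparity_rec, out / "disparity_screen.csv")]
            target_phecodes = sorted({ph for phs in found.values() for ph in phs})
            att = disp.attenuation(
                pheno, merged["group"], config.reference_group, merged["age"], merged["sex"],
                merged["isdi"], phecodes=target_phecodes or None,
                target_groups=[g for g, phs in found.items() if phs] or None,
                alpha=config.alpha, test=config.attenuation_test,
                n_boot=config.n_boot, seed=config.seed + 2,
            )
            files.append(_write(att, out / "attenuation.csv"))
            an = disp.anova_decomposition(merged["isdi"], merged["group"], n_convention=config.anova_convention)
            files.append(_write(pd.DataFrame([dataclasses.asdict(an)]), out / "anova_decomposition.csv"))
            med_records = []
            for g, phs in found.items():
                for ph in phs:
                    med_records.append(
                        disp.mediate_phecode(
                            pheno, ph, merged["group"], g, config.reference_group,
                            merged["isdi"], merged["age"], merged["sex"],
                            n_sims=config.mediation_n_sims, seed=config.seed + 3,
                        )
                    )
            med_df = pd.DataFrame(
                [{k: v for k, v in vars(r).items() if k != "sims"} for r in med_records]
            )
            files.append(_write(med_df, out / "mediation.csv"))
            conc = disp.attenuation_mediation_concordance(att, med_records) if len(att) else {"n": 0, "pearson": np.nan, "spearman": np.nan}
            conc_df = pd.DataFrame([{k: v for k, v in conc.items() if not isinstance(v, pd.DataFrame)}])
            files.append(_write(conc_df, out / "concordance.csv"))
            record("disparities", files, t0)
        except Exception as exc:
            fail("disparities", exc)

    if "report" in stages:
        t0 = time.time()
        try:
            participants = pd.read_csv(out / "participants.csv")
            scores = pd.read_csv(out / "isdi_scores.csv") if (out / "isdi_scores.csv").exists() else None
            summary = summarize_cohort(participants, scores)
            record("report", [_write(summary, out / "cohort_summary.csv")], t0)
        except Exception as exc:
            fail("report", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
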