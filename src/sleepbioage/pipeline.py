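"""End-to-end study emulation.

Stages, in order: synthesize or load cohorts -> exclusions -> train the
four metrics on the reference cohort -> score the target cohort and form
age-acceleration residuals -> code sleep exposures -> PRS and median
split -> categorical / trend / spline dose-response models for the four
outcomes -> stratified and sensitivity analyses -> mediation through
cystatin C and GGT -> report. A run manifest records the configuration
hash, seed, per-stage timings and row counts; rerunning with the same
configuration and seed reproduces identical numeric outputs.
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

from .association import (
    bonferroni_threshold,
    fit_category_model,
    fit_rcs,
    fit_trend_model,
    interaction_wald_test,
)
from .bioage import (
    compute_age_acceleration,
    fit_al_thresholds,
    fit_hd,
    fit_kdm,
    fit_phenoage,
    score_al,
    score_hd,
    score_kdm,
    score_phenoage,
)
from .bioage.serialize import TrainedMetricModels, training_summary
from .cohorts import generate_genotypes, generate_reference_cohort, generate_target_cohort
from .config import SyntheticConfig
from .exposure import (
    CovariateSpec,
    apply_exclusions,
    categorize_sleep_durations,
    compute_sleep_score,
)
from .mediation import fit_mediation, summarize_mediators
from .prs import compute_prs, split_by_prs_median

log = logging.getLogger(__name__)

DEFAULT_OUTCOMES = ("hd", "phenoage_residual", "kdm_residual", "al")

# stratification variables: name -> (column, covariate column to drop from the
# adjustment set when stratifying on it, or None)
SENSITIVITY_EXCLUSIONS = {
    "excluding_shift_workers": ("shift_work", 1),
    "excluding_depression": ("depression", 1),
    "excluding_sleep_disorders": ("sleep_disorder", 1),
    "excluding_poor_health": ("health_rating", 3),
}


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int | None = None  # overrides synthetic.seed when given
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    n_outcome_families: int = 5
    run_genotypes: bool = True
    run_stratified: bool = True
    run_sensitivity: bool = True
    run_mediation: bool = True
    n_boot: int = 1000
    mediation_contrast: str = "squared_deviation"
    al_thresholds_from: str = "target"  # or "reference"
    kdm_use_chronological_term: bool = True
    hd_log1p: bool = False

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=int(self.seed))
        if self.al_thresholds_from not in ("target", "reference"):
            raise ValueError("al_thresholds_from must be 'target' or 'reference'")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        syn = doc.pop("synthetic", {})
        if "outcomes" in doc:
            doc["outcomes"] = tuple(doc["outcomes"])
        return cls(synthetic=SyntheticConfig.from_dict(syn), **doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["outcomes"] = list(self.outcomes)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    """Stable per-stage seed so toggling one stage leaves others unchanged."""
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _spec_without(spec: CovariateSpec, column: str | None) -> CovariateSpec:
    if column is None:
        return spec
    return CovariateSpec(
        continuous=[c for c in spec.continuous if c != column],
        binary=[c for c in spec.binary if c != column],
        categorical={k: v for k, v in spec.categorical.items() if k != column},
    )


def _stratum_variables(table: pd.DataFrame, has_prs: bool) -> list[tuple[str, str, str | None]]:
    """(label, stratum column, covariate to drop) for every stratified analysis."""
    out = [
        ("age_over_60", "stratum_age_over_60", None),
        ("sex", "sex_label", "sex"),
        ("bmi_over_30", "stratum_bmi_over_30", None),
        ("smoking", "smoking_label", "smoking"),
        ("drinking", "drinking_label", "drinking"),
        ("education", "education_label", "education"),
        ("tdi_tertile", "stratum_tdi_tertile", None),
        ("phys_activity", "phys_activity_label", "phys_activity"),
        ("sleep_pattern", "sleep_pattern", None),
    ]
    for flag in ("chronotype_morning", "no_insomnia", "no_daytime_sleepiness", "no_snoring"):
        out.append((flag, f"{flag}_label", None))
    if has_prs:
        out.append(("prs_median", "prs_stratum", None))
    return out


def _add_stratum_columns(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    t["stratum_age_over_60"] = np.where(t["age"] > 60, "over60", "60_or_under")
    t["stratum_bmi_over_30"] = np.where(t["bmi"] > 30, "over30", "30_or_under")
    tert = t["tdi"].quantile([1 / 3, 2 / 3]).to_numpy()
    t["stratum_tdi_tertile"] = np.select(
        [t["tdi"] <= tert[0], t["tdi"] <= tert[1]], ["low", "mid"], default="high"
    )
    for col, (a, b) in {
        "sex_label": ("male", "female"),
        "smoking_label": ("no", "yes"),
        "drinking_label": ("no", "yes"),
        "education_label": ("lower", "higher"),
    }.items():
        src = col.replace("_label", "")
        t[col] = np.where(t[src].astype(int) == 0, a, b)
    t["phys_activity_label"] = t["phys_activity"].map({0: "low", 1: "moderate", 2: "high"})
    for flag in ("chronotype_morning", "no_insomnia", "no_daytime_sleepiness", "no_snoring"):
        t[f"{flag}_label"] = np.where(t[flag].astype(int) == 1, "yes", "no")
    return t


def train_metrics(
    reference: pd.DataFrame,
    config: PipelineConfig,
) -> TrainedMetricModels:
    panel = config.synthetic.panel
    kdm = fit_kdm(reference, panel)
    pheno = fit_phenoage(reference, panel)
    hd = fit_hd(reference, panel)
    al = fit_al_thresholds(reference, panel) if config.al_thresholds_from == "reference" else None
    return TrainedMetricModels(
        panel=panel,
        kdm=kdm,
        phenoage=pheno,
        hd=hd,
        al=al,
        training_summary=training_summary(reference),
    )


def score_metrics(
    target: pd.DataFrame, models: TrainedMetricModels, config: PipelineConfig
) -> pd.DataFrame:
    t = target.copy()
    t["kdm"] = score_kdm(models.kdm, t, use_chronological_term=config.kdm_use_chronological_term)
    t["phenoage"] = score_phenoage(models.phenoage, t)
    t["hd"] = score_hd(models.hd, t)
    al = models.al if models.al is not None else fit_al_thresholds(t, models.panel)
    t["al"] = score_al(al, t)
    return compute_age_acceleration(t)


def _category_results_frame(results: dict[str, "object"]) -> pd.DataFrame:
    rows = []
    for outcome, res in results.items():
        terms = res.terms.copy()
        terms.insert(0, "outcome", outcome)
        rows.append(terms)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Execute every enabled stage and write tables under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.synthetic.seed
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "stages": {},
    }
    results: dict = {"manifest": manifest}
    spec = CovariateSpec()
    alpha = bonferroni_threshold(config.n_outcome_families)

    current_stage = {"name": None}

    def stage(name):
        current_stage["name"] = name
        t0 = time.perf_counter()

        def done(rows_in=None, rows_out=None):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "rows_in": rows_in,
                "rows_out": rows_out,
            }

        return done

    try:
        done = stage("synthesize")
        reference = generate_reference_cohort(config.synthetic)
        target = generate_target_cohort(config.synthetic)
        done(rows_out=len(target))

        done = stage("exclusions")
        target, ledger = apply_exclusions(target)
        ledger.to_csv(out / "exclusion_ledger.tsv", sep="\t", index=False)
        done(rows_in=int(ledger["removed"].sum() + len(target)), rows_out=len(target))

        done = stage("train_metrics")
        models = train_metrics(reference, config)
        models.to_json(str(out / "trained_models.json"))
        done(rows_in=len(reference))

        done = stage("score_metrics")
        target = score_metrics(target, models, config)
        done(rows_out=len(target))

        done = stage("exposure_coding")
        target["sleep_category"] = categorize_sleep_durations(target["sleep_hours"])
        target = compute_sleep_score(target)
        done(rows_out=len(target))

        if config.run_genotypes:
            done = stage("prs")
            dosages, weights = generate_genotypes(
                config.synthetic, participant_ids=list(target["participant_id"])
            )
            prs = compute_prs(weights, dosages)
            target = target.set_index("participant_id")
            target["prs"] = prs
            target["prs_stratum"] = split_by_prs_median(prs)
            target = target.reset_index()
            weights.to_csv(out / "weights.tsv", sep="\t", index=False)
            done(rows_out=len(target))

        target = _add_stratum_columns(target)
        target.to_csv(out / "participants.tsv", sep="\t", index=False)

        done = stage("associations")
        cat_results, trend_rows, rcs_rows, curves = {}, [], [], []
        for outcome in config.outcomes:
            cat_results[outcome] = fit_category_model(target, outcome, spec)
            tr = fit_trend_model(target, outcome, spec)
            row = tr.term("sleep_trend")
            trend_rows.append(
                {"outcome": outcome, "beta": row["beta"], "se": row["se"],
                 "ci_low": row["ci_low"], "ci_high": row["ci_high"], "p": row["p"]}
            )
            rcs = fit_rcs(target, outcome, spec)
            rcs_rows.append(
                {
                    "outcome": outcome,
                    "knot1": rcs.knots[0],
                    "knot2": rcs.knots[1],
                    "knot3": rcs.knots[2],
                    "p_overall": rcs.p_overall,
                    "p_nonlinear": rcs.p_nonlinear,
                    "significant_nonlinear": rcs.p_nonlinear < alpha,
                }
            )
            c = rcs.curve.copy()
            c.insert(0, "outcome", outcome)
            curves.append(c)
        cat_table = _category_results_frame(cat_results)
        cat_table["significant"] = cat_table["p"] < alpha
        cat_table.to_csv(out / "association_category.tsv", sep="\t", index=False)
        pd.DataFrame(trend_rows).assign(significant=lambda d: d["p"] < alpha).to_csv(
            out / "association_trend.tsv", sep="\t", index=False
        )
        pd.DataFrame(rcs_rows).to_csv(out / "association_rcs.tsv", sep="\t", index=False)
        pd.concat(curves, ignore_index=True).to_csv(
            out / "rcs_curves.tsv", sep="\t", index=False
        )
        results["category"] = cat_results
        results["rcs"] = pd.DataFrame(rcs_rows)
        done(rows_in=len(target))

        if config.run_stratified:
            done = stage("stratified")
            strat_rows = []
            for label, column, drop in _stratum_variables(target, "prs_stratum" in target):
                sspec = _spec_without(spec, drop)
                for outcome in config.outcomes:
                    try:
                        p_int, per = interaction_wald_test(target, outcome, column, sspec)
                    except ValueError as err:
                        strat_rows.append(
                            {"stratifier": label, "outcome": outcome,
                             "p_interaction": float("nan"), "note": str(err)}
                        )
                        continue
                    strat_rows.append(
                        {"stratifier": label, "outcome": outcome,
                         "p_interaction": p_int, "note": ""}
                    )
            pd.DataFrame(strat_rows).to_csv(
                out / "stratified_interactions.tsv", sep="\t", index=False
            )
            done(rows_in=len(target))

        if config.run_sensitivity:
            done = stage("sensitivity")
            sens_rows = []
            for label, (col, bad_value) in SENSITIVITY_EXCLUSIONS.items():
                sub = target.loc[target[col].astype(int) != bad_value]
                for outcome in config.outcomes:
                    res = fit_category_model(sub, outcome, spec)
                    terms = res.terms.copy()
                    terms.insert(0, "outcome", outcome)
                    terms.insert(0, "analysis", label)
                    terms["n"] = res.n
                    sens_rows.append(terms)
            pd.concat(sens_rows, ignore_index=True).to_csv(
                out / "sensitivity_category.tsv", sep="\t", index=False
            )
            done(rows_in=len(target))

        if config.run_mediation:
            done = stage("mediation")
            med_results = []
            for outcome in config.outcomes:
                for mediator in ("cysc", "ggt"):
                    med_results.append(
                        fit_mediation(
                            target,
                            outcome,
                            mediator,
                            spec,
                            contrast=config.mediation_contrast,
                            n_boot=config.n_boot,
                            seed=_stage_seed(seed, f"mediation:{outcome}:{mediator}"),
                        )
                    )
            med_table = summarize_mediators(med_results)
            med_table.to_csv(out / "mediation.tsv", sep="\t", index=False)
            with open(out / "mediation.json", "w") as fh:
                json.dump(
                    [dataclasses.asdict(r) for r in med_results], fh, indent=1,
                    sort_keys=True,
                )
            results["mediation"] = med_table
            done(rows_in=len(target))
    except Exception as err:
        manifest["failed_stage"] = current_stage["name"]
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["target"] = target
    return results
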