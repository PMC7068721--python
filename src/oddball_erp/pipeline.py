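"""End-to-end study runner: simulate -> preprocess -> measure -> markers
-> statistics, with provenance logging and file outputs.

Every stochastic stage draws from a seed recorded in the run config, so
a run is reproducible end to end; the provenance log stores the config
hash, seeds and package versions alongside per-subject retention counts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .components import get_window, measure_components
from .containers import CONDITIONS
from .design import ConfigurationError, DesignSpec
from .markers import build_marker_table, delta_p3, habituation_table
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import generate_cohort
from .stats import (
    AnovaResults,
    correlate_and_compare,
    fdr_correct,
    hierarchical_regression,
    mixed_rm_anova,
)
from .templates import AGE_POINTS, PRESETS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML round-trippable)."""

    out_dir: str = "results"
    cohorts: list[str] = field(default_factory=lambda: ["UK", "Gambia"])
    n_per_cohort: int = 20
    design: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    noise_sd_uv: float = 5.0
    drift_amplitude_uv: float = 20.0
    artifact_epoch_fraction: float = 0.05
    seed: int = 0
    equalize_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cohort < 2:
            raise ConfigurationError("n_per_cohort must be >= 2")
        for name in self.cohorts:
            if name not in PRESETS:
                raise ConfigurationError(
                    f"unknown cohort preset {name!r}; "
                    f"available: {sorted(PRESETS)}")

    def design_spec(self) -> DesignSpec:
        return DesignSpec(**self.design)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(equalize_seed=self.equalize_seed,
                                **self.preprocess)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResults:
    """Everything one run produces, in memory."""

    config: RunConfig
    measures: pd.DataFrame
    habituation: pd.DataFrame
    markers: pd.DataFrame
    qc: pd.DataFrame
    anova_p3: AnovaResults | None
    anova_habituation: AnovaResults | None
    correlations: dict | None
    regressions: dict
    fdr: dict
    provenance: dict

    def summary(self) -> str:
        parts = [f"Oddball ERP study run (config {self.provenance['config_hash']})",
                 f"  subjects included at both ages: "
                 f"{self.markers['subject_id'].nunique()}"]
        if self.anova_p3 is not None:
            parts += ["", "P3 mean amplitude:", self.anova_p3.summary()]
        if self.anova_habituation is not None:
            parts += ["", "Habituation score:",
                      self.anova_habituation.summary()]
        if self.correlations and self.correlations["comparison"]:
            comp = self.correlations["comparison"]
            for g, r in self.correlations["groups"].items():
                parts.append(
                    f"delta-P3 vs outcome, {g}: r = {r.statistic:.3f}, "
                    f"p = {r.p:.3f} (n = {r.extra.get('n')})")
            parts.append(
                f"correlation comparison: z = {comp.statistic:.3f}, "
                f"one-sided p = {comp.p:.3f}")
        for mid, reg in self.regressions.items():
            parts += ["", reg.summary()]
        return "\n".join(parts)


def _stage_error(stage: str, subject: str, err: Exception) -> RuntimeError:
    return RuntimeError(f"stage {stage!r} failed for subject "
                        f"{subject!r}: {err}")


def run_pipeline(cfg: RunConfig, write: bool = True) -> StudyResults:
    """Execute the full study and (optionally) write the report bundle."""
    design = cfg.design_spec()
    pcfg = cfg.preprocess_config()
    rng = np.random.default_rng(cfg.seed)

    measures_rows: list[pd.DataFrame] = []
    hab_rows: list[pd.DataFrame] = []
    qc_rows: list[dict] = []
    covariates: list[pd.DataFrame] = []

    for cohort_name in cfg.cohorts:
        truth = PRESETS[cohort_name]()
        try:
            dataset = generate_cohort(
                truth, cfg.n_per_cohort,
                seed=int(rng.integers(2 ** 31)),
                design=design,
                noise_sd_uv=cfg.noise_sd_uv,
                drift_amplitude_uv=cfg.drift_amplitude_uv,
                artifact_epoch_fraction=cfg.artifact_epoch_fraction,
            )
        except Exception as err:
            raise _stage_error("simulate", cohort_name, err)
        covariates.append(dataset.truth_table)

        for subj in dataset.subjects:
            for age in AGE_POINTS:
                rec = subj.recordings[age]
                try:
                    es, decision = preprocess_recording(rec, pcfg)
                except Exception as err:
                    raise _stage_error("preprocess", subj.subject_id, err)
                qc_rows.append({
                    "subject_id": subj.subject_id, "cohort": cohort_name,
                    "age_point": age, "included": decision.included,
                    **{f"n_{c}": decision.counts.get(c, 0)
                       for c in CONDITIONS},
                })
                if not decision.included:
                    continue
                try:
                    m = measure_components(es, age,
                                           subject_id=subj.subject_id)
                    m["cohort"] = cohort_name
                    measures_rows.append(m)
                    h = habituation_table({subj.subject_id: es}, age,
                                          get_window(age, "P3"))
                    h["cohort"] = cohort_name
                    hab_rows.append(h)
                except Exception as err:
                    raise _stage_error("components", subj.subject_id, err)

    measures = (pd.concat(measures_rows, ignore_index=True)
                if measures_rows else pd.DataFrame())
    habituation = (pd.concat(hab_rows, ignore_index=True)
                   if hab_rows else pd.DataFrame())
    qc = pd.DataFrame(qc_rows)
    covar = pd.concat(covariates, ignore_index=True)

    # markers: delta-P3 for subjects usable at both ages
    delta = delta_p3(measures) if len(measures) else pd.DataFrame()
    markers = (build_marker_table(delta, covar) if len(delta)
               else pd.DataFrame())

    # --- statistics ---
    anova_p3 = anova_hab = None
    correlations = None
    regressions: dict[int, object] = {}
    fdr: dict[str, object] = {}

    if len(measures):
        p3 = measures[measures["component"] == "P3"]
        both = p3.groupby("subject_id")["age_point"].nunique()
        complete = both[both == 2].index
        p3c = p3[p3["subject_id"].isin(complete)]
        if p3c["subject_id"].nunique() >= 4:
            anova_p3 = mixed_rm_anova(
                p3c, dv="mean_amp_uv", within=["condition", "age_point"],
                subject="subject_id",
                between="cohort" if len(cfg.cohorts) > 1 else None)
    if len(habituation):
        both = habituation.groupby("subject_id")["age_point"].nunique()
        complete = both[both == 2].index
        habc = habituation[habituation["subject_id"].isin(complete)]
        if habc["subject_id"].nunique() >= 4:
            anova_hab = mixed_rm_anova(
                habc, dv="habituation_uv",
                within=["condition", "age_point"], subject="subject_id",
                between="cohort" if len(cfg.cohorts) > 1 else None)

    if len(markers) and markers["cohort"].nunique() == 2 \
            and markers.groupby("cohort").size().min() >= 4:
        correlations = correlate_and_compare(
            markers["delta_p3"], markers["outcome"], markers["cohort"])
    if len(markers) >= 10:
        for mid in (1, 2):
            regressions[mid] = hierarchical_regression(markers, mid)
        anthro_p = [regressions[m].pvalues[
            regressions[m].selected_predictor] for m in (1, 2)]
        fdr["anthropometric_p_fdr"] = fdr_correct(anthro_p).tolist()

    provenance = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "equalize_seed": cfg.equalize_seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n_included": {
            f"{row['cohort']}_{row['age_point']}": int(row["included"])
            for _, row in qc.iterrows()} if len(qc) else {},
    }

    results = StudyResults(
        config=cfg, measures=measures, habituation=habituation,
        markers=markers, qc=qc, anova_p3=anova_p3,
        anova_habituation=anova_hab, correlations=correlations,
        regressions=regressions, fdr=fdr, provenance=provenance,
    )
    if write:
        write_outputs(results)
    return results


def write_outputs(results: StudyResults) -> None:
    out = Path(results.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.measures.to_csv(out / "measures.tsv", sep="\t", index=False)
    results.habituation.to_csv(out / "habituation.tsv", sep="\t",
                               index=False)
    results.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    results.qc.to_csv(out / "qc.tsv", sep="\t", index=False)

    stats_json: dict = {}
    if results.anova_p3 is not None:
        stats_json["anova_p3"] = results.anova_p3.to_frame().to_dict(
            orient="records")
    if results.anova_habituation is not None:
        stats_json["anova_habituation"] = (
            results.anova_habituation.to_frame().to_dict(orient="records"))
    if results.correlations is not None:
        stats_json["correlations"] = {
            g: {"r": r.statistic, "p": r.p, "n": r.extra.get("n")}
            for g, r in results.correlations["groups"].items()}
        comp = results.correlations["comparison"]
        if comp is not None:
            stats_json["correlation_comparison"] = {
                "z": comp.statistic, "p_one_sided": comp.p,
                "p_two_sided": comp.extra["p_two_sided"]}
    for mid, reg in results.regressions.items():
        stats_json[f"model_{mid}"] = {
            "selected_predictor": reg.selected_predictor,
            "rsq_null": reg.rsq_null, "rsq_full": reg.rsq_full,
            "rsq_change": reg.rsq_change, "f_change": reg.f_change,
            "p_change": reg.p_change,
            "t_delta_p3": float(reg.tvalues["delta_p3"]),
            "p_delta_p3": float(reg.pvalues["delta_p3"]),
        }
    stats_json.update(results.fdr)
    (out / "stats.json").write_text(json.dumps(stats_json, indent=1))

    qc_summary = (
        results.qc.groupby(["cohort", "age_point"])
        .agg(n_subjects=("subject_id", "nunique"),
             n_included=("included", "sum"))
        .reset_index().to_dict(orient="records")
    ) if len(results.qc) else []
    (out / "provenance.json").write_text(json.dumps(
        {**results.provenance, "qc_summary": qc_summary}, indent=1))
    (out / "summary.txt").write_text(results.summary() + "\n")
    logger.info("wrote report bundle to %s", out)
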