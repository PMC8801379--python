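"""Configuration, tabular I/O, and the end-to-end analysis driver.

The pipeline sequences the full analysis: simulate (or load) cohorts ->
quantify flow events into per-sample FVA summaries -> fit or load the RCS
logistic model -> score and call CR-B -> evaluate per-cohort and combined
diagnostic metrics -> reclassify VUS for CR-B- carriers -> write a report.

All tables are comma-separated UTF-8 text with a header row and "." decimal;
models and reports are schema-versioned JSON.  Every output records the run
seed and a hash of the resolved configuration, and the whole run is
deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .fva_quantify import (
    ASSAY_FIELDS,
    ReplicateStats,
    quantify_sample_pair,
    replicate_cv,
    results_to_frame,
)
from .performance import (
    CohortMetrics,
    CombinedMetrics,
    METRIC_KEYS,
    cohort_confusion_metrics,
    combine_weighted_metrics,
)
from .rcs_model import (
    BENIGN_LABEL,
    PATHOGENIC_LABEL,
    RCSModel,
    assess_bimodality,
    classify_crb,
    fit_rcs_model,
    score_table,
)
from .synthetic_data import (
    GeneratorConfig,
    SampleSpec,
    Subject,
    generate_cohort,
    generate_control_cohort,
    simulate_replicate_pairs,
)
from .vus_bayes import (
    ClassificationBands,
    likelihood_ratios_from_assay,
    reclassify_over_prior_grid,
    reclassify_variants,
)

log = logging.getLogger("crbflow")

SUBJECT_COLUMNS = [
    "subject_id",
    "cohort",
    "group",
    "gene",
    "variant_class",
    "true_phenotype",
    "cancer_status",
]

# Single-feature assay -> feature-column mapping for per-assay calls.
ASSAY_FEATURES = {"brca1": "brca1_nl", "brca2": "brca2_nl", "p53": "p53_ratio"}

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Subject-table I/O
# ---------------------------------------------------------------------------

def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in subjects], columns=SUBJECT_COLUMNS)


def read_subject_table(path) -> list[Subject]:
    """Read and validate a subject table (CSV; BOM and CRLF tolerated)."""
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"subject table {path}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"subject table {path}: duplicate subject ids {dupes}")
    subjects = []
    for idx, row in df.iterrows():
        try:
            subj = Subject(
                subject_id=str(row["subject_id"]),
                cohort=str(row["cohort"]),
                group=int(row["group"]),
                gene=str(row["gene"]),
                variant_class=str(row["variant_class"]),
                true_phenotype=str(row["true_phenotype"]),
                cancer_status=str(row["cancer_status"]),
            )
            subj.validate()
        except (InputError, ValueError) as exc:
            raise InputError(f"subject table {path}, row {idx + 1}: {exc}") from exc
        subjects.append(subj)
    return subjects


def write_subject_table(subjects: list[Subject], path) -> None:
    """Write the canonical form: UTF-8, LF line endings, fixed column order."""
    subjects_to_frame(subjects).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """One cohort to simulate: a fixed-composition control panel or a clinic
    cohort drawn from prevalences (overriding the generator defaults)."""

    label: str
    kind: str = "clinic"  # "clinic" or "control"
    n_subjects: int = 50
    n_carriers: int = 22
    n_relatives: int = 14
    plp_prevalence: float | None = None
    vus_prevalence: float | None = None
    relative_prevalence: float | None = None

    def validate(self) -> None:
        if self.kind not in ("clinic", "control"):
            raise ConfigurationError(f"cohort {self.label}: kind must be clinic or control")
        if self.kind == "clinic" and self.n_subjects < 1:
            raise ConfigurationError(f"cohort {self.label}: n_subjects must be >= 1")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    output_dir: str = "crbflow_out"
    seed: int = 0
    subject_table: str | None = None  # load instead of simulating cohorts
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohorts: list[CohortSpec] = field(default_factory=list)
    model_mode: str = "fit"  # "fit" or "load"
    model_path: str | None = None
    train_cohort: str = "coriell"
    evidence_sensitivity: float = 0.91
    evidence_specificity: float = 0.96
    reclassification_prior: float = 0.5
    bands: ClassificationBands = field(default_factory=ClassificationBands)
    log_level: str = "INFO"

    def validate(self) -> None:
        self.generator.validate()
        if self.model_mode not in ("fit", "load"):
            raise ConfigurationError("model_mode must be 'fit' or 'load'")
        if self.model_mode == "load" and not self.model_path:
            raise ConfigurationError("model_mode 'load' requires model_path")
        if self.subject_table is None and not self.cohorts:
            raise ConfigurationError("either subject_table or cohorts must be given")
        for c in self.cohorts:
            c.validate()
        if not 0.0 < self.evidence_sensitivity <= 1.0:
            raise ConfigurationError("evidence_sensitivity must be in (0, 1]")
        if not 0.0 < self.evidence_specificity <= 1.0:
            raise ConfigurationError("evidence_specificity must be in (0, 1]")
        if not 0.0 < self.reclassification_prior < 1.0:
            raise ConfigurationError("reclassification_prior must be in (0, 1)")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        gen_doc = doc.pop("generator", {}) or {}
        gen = GeneratorConfig(**gen_doc)
        cohorts = [CohortSpec(**c) for c in doc.pop("cohorts", []) or []]
        bands_doc = doc.pop("bands", None)
        bands = ClassificationBands(**bands_doc) if bands_doc else ClassificationBands()
        cfg = cls(generator=gen, cohorts=cohorts, bands=bands, **doc)
        cfg.generator = replace(cfg.generator, rng_seed=cfg.seed)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        try:
            return cls.from_dict(doc)
        except TypeError as exc:
            raise ConfigurationError(f"config file {path}: {exc}") from exc

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs land
        and how verbosely we log do not change the science)."""
        doc = dataclasses.asdict(self)
        doc.pop("output_dir", None)
        doc.pop("log_level", None)
        blob = json.dumps(doc, sort_keys=True, default=str).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def default_demo_config(
    seed: int = 0,
    output_dir: str = "crbflow_out",
    events_per_sample: int = 10_000,
    n_replicates: int = 3,
) -> PipelineConfig:
    """Three-cohort demo: a 36-subject control panel (22 carriers / 14
    relatives) used for training, plus two clinic cohorts of 100 and 59
    subjects with carrier prevalences of 8% and 20%."""
    gen = GeneratorConfig(
        events_per_sample=events_per_sample, n_replicates=n_replicates, rng_seed=seed
    )
    cfg = PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        generator=gen,
        cohorts=[
            CohortSpec(label="coriell", kind="control", n_carriers=22, n_relatives=14),
            CohortSpec(
                label="montefiore",
                kind="clinic",
                n_subjects=100,
                plp_prevalence=0.08,
                vus_prevalence=0.34,
                relative_prevalence=0.04,
            ),
            CohortSpec(
                label="northwell",
                kind="clinic",
                n_subjects=59,
                plp_prevalence=0.20,
                vus_prevalence=0.39,
                relative_prevalence=0.0,
            ),
        ],
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Everything one pipeline run computed, plus provenance."""

    per_cohort_metrics: list[CohortMetrics]
    combined_metrics: CombinedMetrics
    crb_summary: pd.DataFrame
    bimodality: dict
    cv_qc: dict
    reclassification: pd.DataFrame
    prior_grid_table: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        def metric_block(metrics: dict) -> dict:
            return {
                assay: {
                    m: (
                        {
                            "value": mv.value,
                            "numerator": mv.numerator,
                            "denominator": mv.denominator,
                        }
                        if mv.available
                        else None
                    )
                    for m, mv in block.items()
                }
                for assay, block in metrics.items()
            }

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "per_cohort_metrics": {
                cm.cohort: {"n_total": cm.n_total, "metrics": metric_block(cm.metrics)}
                for cm in self.per_cohort_metrics
            },
            "combined_metrics": {
                "weights": self.combined_metrics.weights,
                "caveat": self.combined_metrics.caveat,
                "metrics": metric_block(self.combined_metrics.metrics),
            },
            "crb_summary": self.crb_summary.to_dict(orient="records"),
            "bimodality": self.bimodality,
            "cv_qc": self.cv_qc,
            "reclassification": self.reclassification.to_dict(orient="records"),
            "prior_grid": self.prior_grid_table.to_dict(orient="records"),
        }


def render_metrics_text(
    per_cohort: list[CohortMetrics], combined: CombinedMetrics
) -> str:
    """Validation-table layout: metric rows x assay columns per cohort."""
    assays = list(combined.metrics)
    lines = []
    header = f"{'Cohort':<22}{'Metric':<14}" + "".join(f"{a.upper():<16}" for a in assays)
    lines.append(header)
    lines.append("-" * len(header))

    def block(name: str, metrics: dict) -> None:
        for metric in METRIC_KEYS:
            row = f"{name:<22}{metric.capitalize():<14}"
            for assay in assays:
                mv = metrics.get(assay)
                row += f"{(mv[metric].render() if mv else 'NA'):<16}"
            lines.append(row.rstrip())
            name = ""

    for cm in per_cohort:
        block(f"{cm.cohort} (N={cm.n_total})", cm.metrics)
    total_n = sum(combined.weights.values())
    block(f"All cohorts (N={total_n})", combined.metrics)
    lines.append("")
    lines.append(f"Note: {combined.caveat}")
    return "\n".join(lines) + "\n"


def write_report(report: RunReport, out_dir, formats=("json", "text")) -> dict[str, Path]:
    """Write report.json and/or report.txt; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(report.to_dict(), indent=2, default=_json_default) + "\n",
            encoding="utf-8",
        )
        written["json"] = path
    if "text" in formats:
        path = out_dir / "report.txt"
        text = render_metrics_text(report.per_cohort_metrics, report.combined_metrics)
        text += "\nCR-B calls\n"
        text += report.crb_summary.to_string(index=False) + "\n"
        text += (
            f"\nBimodality: {report.bimodality.get('bimodal')} "
            f"(BIC margin {report.bimodality.get('statistic', float('nan')):.1f})\n"
        )
        path.write_text(text, encoding="utf-8")
        written["text"] = path
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _stage(name: str, message: str) -> None:
    log.info("[%s] %s", name, message)


def simulate_subjects(config: PipelineConfig) -> list[Subject]:
    subjects: list[Subject] = []
    for spec in config.cohorts:
        gen = config.generator
        overrides = {
            k: getattr(spec, k)
            for k in ("plp_prevalence", "vus_prevalence", "relative_prevalence")
            if getattr(spec, k) is not None
        }
        if overrides:
            gen = replace(gen, **overrides)
        if spec.kind == "control":
            subjects.extend(
                generate_control_cohort(gen, spec.n_carriers, spec.n_relatives, spec.label)
            )
        else:
            subjects.extend(generate_cohort(gen, spec.n_subjects, spec.label))
    return subjects


def quantify_subjects(
    subjects: list[Subject], config: PipelineConfig
) -> tuple[pd.DataFrame, list[ReplicateStats]]:
    """Simulate events and quantify each subject's replicates.

    Returns the tidy per-replicate FVA table and per-subject replicate
    statistics.  QC warnings (CV above 3%) are logged, not fatal.
    """
    gen = config.generator
    results = []
    stats_list = []
    for subject in subjects:
        pairs = simulate_replicate_pairs(
            subject, SampleSpec(subject.subject_id), gen.n_replicates, gen
        )
        reps = [
            quantify_sample_pair(
                ch, un, subject_id=subject.subject_id, replicate_index=i + 1
            )
            for i, (ch, un) in enumerate(pairs)
        ]
        results.extend(reps)
        st = replicate_cv(reps)
        stats_list.append(st)
        worst = max(st.cv_percent.values())
        if worst > 3.0:
            log.warning(
                "[quantify] subject %s: replicate CV %.1f%% exceeds 3%%",
                subject.subject_id,
                worst,
            )
    return results_to_frame(results), stats_list


def subject_mean_features(fva_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged features, one row per subject."""
    return (
        fva_table.groupby("subject_id", sort=False)[list(ASSAY_FIELDS)]
        .mean()
        .reset_index()
    )


def fit_models_for_run(
    features: pd.DataFrame, subjects_df: pd.DataFrame, config: PipelineConfig
) -> tuple[RCSModel, dict[str, RCSModel]]:
    """Fit (or load) the 3-feature RCS model plus single-feature assay models.

    Training labels come from the designated training cohort: group 1
    (carriers) is pathogenic-like, group 3 (negative relatives) benign-like.
    """
    train = subjects_df.loc[
        (subjects_df["cohort"] == config.train_cohort)
        & (subjects_df["group"].isin([1, 3]))
    ]
    if train.empty:
        raise InputError(
            f"training cohort '{config.train_cohort}' has no group-1/group-3 subjects"
        )
    merged = train.merge(features, on="subject_id")
    labels = [
        PATHOGENIC_LABEL if g == 1 else BENIGN_LABEL for g in merged["group"]
    ]
    if config.model_mode == "load":
        model = RCSModel.load(config.model_path)
    else:
        model = fit_rcs_model(merged, labels, seed=config.seed)
    assay_models = {
        assay: fit_rcs_model(
            merged, labels, seed=config.seed, feature_names=(feature,)
        )
        for assay, feature in ASSAY_FEATURES.items()
    }
    return model, assay_models


def per_assay_calls(
    features: pd.DataFrame, model: RCSModel, assay_models: dict[str, RCSModel]
) -> pd.DataFrame:
    """Boolean test-positive calls per assay (and RCS) for each subject."""
    calls = pd.DataFrame({"subject_id": features["subject_id"]})
    for assay, m in assay_models.items():
        scored = score_table(m, features)
        calls[assay] = (scored["call"] == "CRB_plus").to_numpy()
    scored = score_table(model, features)
    calls["rcs"] = (scored["call"] == "CRB_plus").to_numpy()
    return calls


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; intermediate tables persist under output_dir."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("subjects", "simulating cohorts" if not config.subject_table else "loading subjects")
    if config.subject_table:
        subjects = read_subject_table(config.subject_table)
    else:
        subjects = simulate_subjects(config)
    subjects_df = subjects_to_frame(subjects)
    write_subject_table(subjects, out / "subjects.csv")

    _stage("quantify", f"quantifying {len(subjects)} subjects x {config.generator.n_replicates} replicates")
    fva_table, rep_stats = quantify_subjects(subjects, config)
    fva_table.to_csv(out / "fva_results.csv", index=False, lineterminator="\n")
    cv_rows = pd.DataFrame(
        [
            {"subject_id": st.subject_id, **{f"cv_{k}": v for k, v in st.cv_percent.items()}}
            for st in rep_stats
        ]
    )
    cv_rows.to_csv(out / "replicate_stats.csv", index=False, lineterminator="\n")
    cv_cols = [c for c in cv_rows.columns if c.startswith("cv_")]
    cv_matrix = cv_rows[cv_cols].to_numpy()
    cv_qc = {
        "mean_cv_percent": {
            c.removeprefix("cv_"): float(cv_rows[c].mean()) for c in cv_cols
        },
        "fraction_cvs_above_3pct": float((cv_matrix > 3.0).mean()),
        "n_replicates": config.generator.n_replicates,
    }

    _stage("model", f"{config.model_mode}ting RCS model on cohort '{config.train_cohort}'")
    features = subject_mean_features(fva_table)
    model, assay_models = fit_models_for_run(features, subjects_df, config)
    model.save(out / "model.json")

    _stage("score", "scoring all subjects")
    rcs_results = score_table(model, features)
    rcs_results.to_csv(out / "rcs_results.csv", index=False, lineterminator="\n")
    crb_summary = classify_crb(rcs_results, subjects_df)
    bimodality = (
        assess_bimodality(rcs_results["rcs"], seed=config.seed)
        if len(rcs_results) >= 20
        else {"bimodal": None, "note": "fewer than 20 subjects"}
    )

    _stage("evaluate", "computing per-cohort and combined metrics")
    calls = per_assay_calls(features, model, assay_models)
    per_cohort = [
        cohort_confusion_metrics(calls, subjects_df, cohort)
        for cohort in subjects_df["cohort"].unique()
    ]
    combined = combine_weighted_metrics(per_cohort)

    _stage("reclassify", "Bayesian VUS reclassification for CR-B- carriers")
    evidence = likelihood_ratios_from_assay(
        config.evidence_sensitivity, config.evidence_specificity
    )
    vus_subjects = subjects_df.loc[subjects_df["variant_class"] == "VUS"]
    variants = vus_subjects.merge(
        rcs_results[["subject_id", "call"]], on="subject_id"
    ).rename(columns={"call": "crb_call"})[
        ["subject_id", "gene", "variant_class", "crb_call"]
    ]
    reclassification = reclassify_variants(
        variants, evidence, prior=config.reclassification_prior, bands=config.bands
    )
    reclassification.to_csv(out / "reclassification.csv", index=False, lineterminator="\n")
    grid = reclassify_over_prior_grid(evidence, "CRB_minus", bands=config.bands)

    report = RunReport(
        per_cohort_metrics=per_cohort,
        combined_metrics=combined,
        crb_summary=crb_summary,
        bimodality=bimodality,
        cv_qc=cv_qc,
        reclassification=reclassification,
        prior_grid_table=grid.table,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "evidence": {
                "sensitivity": config.evidence_sensitivity,
                "specificity": config.evidence_specificity,
                "lr_negative": evidence.lr_negative,
                "max_blb_prior": grid.max_blb_prior,
            },
        },
    )
    _stage("report", f"writing report to {out}")
    write_report(report, out)
    return report
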