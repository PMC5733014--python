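"""End-to-end study orchestration: QC → phenotype → cell imputation →
five association scans → annotation, thresholds, overlap and enrichment.

The five scans share a single QC-filtered probe set: paired and unpaired
analyses of cross-sectional cognition (follow-up composite) and of the
10-year change score, plus the paired cross-sectional scan restricted to
the 50% most discordant pairs. Individuals lacking the composite needed by
a given analysis are dropped per-analysis, not globally.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_composition import fit_cell_imputer, impute_missing_counts
from .data_model import (
    Annotation,
    BetaMatrix,
    CellCounts,
    GeneSetCollection,
    ProbeQCMetrics,
    SampleSheet,
    ValidationError,
    _write_tsv,
    read_annotation,
    read_beta_matrix,
    read_cell_counts,
    read_gmt,
    read_qc_metrics,
    read_sample_sheet,
    write_cell_counts,
)
from .enrichment import enrich_all, hits_to_genes
from .paired import build_pair_differences, run_paired_ewas, select_most_discordant
from .phenotype import (
    CognitiveComponents,
    DeclineTestResult,
    compute_change,
    compute_composites,
    read_components,
    test_cohort_decline,
)
from .qc import QCReport, QCThresholds, logit_transform, run_probe_qc
from .reporting import (
    ThresholdConfig,
    annotate_probes,
    manhattan_table,
    overlap_analysis,
    threshold_report,
)
from .unpaired import run_unpaired_ewas

logger = logging.getLogger(__name__)

ANALYSES = [
    "paired-cognition",
    "paired-cognition-discordant50",
    "paired-change",
    "unpaired-cognition",
    "unpaired-change",
]


@dataclass(frozen=True)
class StudySettings:
    qc_thresholds: QCThresholds = QCThresholds()
    thresholds: ThresholdConfig = ThresholdConfig()
    reference_wave: str = "intake"
    epsilon: float = 1e-6
    n_pls_components: int = 10
    discordant_fraction: float = 0.5
    min_set_size: int = 1


@dataclass
class StudyInputs:
    beta: BetaMatrix
    qc_metrics: ProbeQCMetrics
    sample_sheet: SampleSheet
    cell_counts: CellCounts
    components: CognitiveComponents
    annotation: Annotation
    cross_reactive: set[str] = field(default_factory=set)
    gene_sets: GeneSetCollection | None = None


@dataclass
class StudyResult:
    results: dict[str, pd.DataFrame]
    suggestive: dict[str, pd.DataFrame]
    significant: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    overlap: pd.DataFrame
    qc_report: QCReport
    decline: DeclineTestResult
    cell_counts_used: CellCounts
    imputation_skipped: bool
    run_log: dict


def from_cohort(cohort, gene_sets: GeneSetCollection | None = None) -> StudyInputs:
    """Adapt a :class:`~twinewas.simulate.SimulatedCohort` to study inputs."""
    return StudyInputs(
        beta=cohort.beta,
        qc_metrics=cohort.qc_metrics,
        sample_sheet=cohort.sample_sheet,
        cell_counts=cohort.cell_counts,
        components=cohort.components,
        annotation=cohort.annotation,
        cross_reactive=cohort.cross_reactive,
        gene_sets=gene_sets,
    )


def run_study(
    inputs: StudyInputs,
    settings: StudySettings = StudySettings(),
    output_dir=None,
) -> StudyResult:
    """Run every stage on in-memory inputs; optionally write the report
    bundle (result, threshold, overlap, enrichment and Manhattan tables plus
    a JSON run log) to ``output_dir``."""
    log: dict = {"package_version": __version__, "python": platform.python_version(), "stages": {}}

    # --- QC ---------------------------------------------------------------
    kept_beta, qc_report = run_probe_qc(
        inputs.beta, inputs.qc_metrics, inputs.cross_reactive, settings.qc_thresholds
    )
    log["stages"]["qc"] = qc_report.summary()
    mvalues = logit_transform(kept_beta, epsilon=settings.epsilon)

    # --- phenotype --------------------------------------------------------
    composites, _ = compute_composites(inputs.components, settings.reference_wave)
    by_wave = {
        wave: composites[composites["wave"] == wave].set_index("sample_id")
        for wave in ("intake", "followup")
    }
    change = compute_change(by_wave["intake"], by_wave["followup"])
    cognition = by_wave["followup"]["value"]
    decline = test_cohort_decline(change, inputs.sample_sheet)
    log["stages"]["phenotype"] = {
        "n_cognition_followup": int(by_wave["followup"]["available"].sum()),
        "n_cognition_intake": int(by_wave["intake"]["available"].sum()),
        "n_change": int(change["available"].sum()),
        "decline_mean_change": decline.mean_change,
        "decline_p": decline.p_value,
    }

    # --- cell composition -------------------------------------------------
    complete = inputs.cell_counts.complete_mask()
    all_samples = set(inputs.sample_sheet.sample_ids)
    measured = set(complete.index[complete]) & all_samples
    imputation_skipped = measured >= all_samples
    if imputation_skipped:
        logger.info("all samples have measured cell counts; imputation skipped")
        counts_used = inputs.cell_counts
    else:
        model = fit_cell_imputer(
            kept_beta, inputs.sample_sheet, inputs.cell_counts, settings.n_pls_components
        )
        counts_used = impute_missing_counts(model, kept_beta, inputs.sample_sheet, inputs.cell_counts)
    log["stages"]["cell_composition"] = {
        "skipped": imputation_skipped,
        "n_imputed": int(counts_used.data["imputed"].sum()),
    }

    # --- association scans ------------------------------------------------
    results: dict[str, pd.DataFrame] = {}
    design_cog = build_pair_differences(mvalues, inputs.sample_sheet, cognition, counts_used)
    results["paired-cognition"] = run_paired_ewas(design_cog, analysis="paired-cognition")
    discordant = select_most_discordant(design_cog, settings.discordant_fraction)
    results["paired-cognition-discordant50"] = run_paired_ewas(
        discordant, analysis="paired-cognition-discordant50"
    )
    design_chg = build_pair_differences(mvalues, inputs.sample_sheet, change["value"], counts_used)
    results["paired-change"] = run_paired_ewas(design_chg, analysis="paired-change")
    results["unpaired-cognition"] = run_unpaired_ewas(
        mvalues, inputs.sample_sheet, cognition, counts_used, analysis="unpaired-cognition"
    )
    results["unpaired-change"] = run_unpaired_ewas(
        mvalues, inputs.sample_sheet, change["value"], counts_used, analysis="unpaired-change"
    )
    for name, table in results.items():
        log["stages"][name] = {
            "n_probes": int(len(table)),
            "n_units": int(table["n_units"].max()) if len(table) else 0,
        }

    # --- reporting --------------------------------------------------------
    annotated = {n: annotate_probes(t, inputs.annotation) for n, t in results.items()}
    suggestive, significant = {}, {}
    for name, table in annotated.items():
        suggestive[name], significant[name] = threshold_report(table, settings.thresholds)
    overlap = overlap_analysis(results, inputs.annotation, settings.thresholds.overlap_p).to_frame()

    enrichment: dict[str, pd.DataFrame] = {}
    if inputs.gene_sets is not None:
        for name, table in results.items():
            hit_genes = hits_to_genes(table, inputs.annotation, settings.thresholds.overlap_p)
            if not hit_genes:
                logger.info("%s: no hit genes at p < %g; enrichment skipped", name, settings.thresholds.overlap_p)
                continue
            enrichment[name] = enrich_all(
                hit_genes, inputs.gene_sets, inputs.annotation, settings.min_set_size
            )

    result = StudyResult(
        results=annotated,
        suggestive=suggestive,
        significant=significant,
        enrichment=enrichment,
        overlap=overlap,
        qc_report=qc_report,
        decline=decline,
        cell_counts_used=counts_used,
        imputation_skipped=imputation_skipped,
        run_log=log,
    )
    if output_dir is not None:
        _write_bundle(result, inputs, Path(output_dir))
    return result


def _write_bundle(result: StudyResult, inputs: StudyInputs, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.write(out / "qc_report.tsv", out / "qc_summary.json")
    write_cell_counts(result.cell_counts_used, out / "cell_counts_used.tsv")
    for name, table in result.results.items():
        _write_tsv(table, out / f"results_{name}.tsv")
        _write_tsv(result.suggestive[name], out / f"suggestive_{name}.tsv")
        _write_tsv(result.significant[name], out / f"significant_{name}.tsv")
        _write_tsv(manhattan_table(table), out / f"manhattan_{name}.tsv")
    _write_tsv(result.overlap, out / "overlap.tsv")
    for name, table in result.enrichment.items():
        _write_tsv(table, out / f"enrichment_{name}.tsv")
    with open(out / "run_log.json", "w") as handle:
        json.dump(result.run_log, handle, indent=2, default=float)


# ---------------------------------------------------------------------------
# file-based entry point


@dataclass
class StudyConfig:
    """Paths plus settings, loadable from YAML for the command line."""

    beta: str
    bead_count: str
    detection_p: str
    signal_zero: str
    sample_sheet: str
    cell_counts: str
    components: str
    annotation: str
    output_dir: str
    cross_reactive: str | None = None
    gmt: str | None = None
    settings: StudySettings = StudySettings()

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        settings_raw = raw.pop("settings", {}) or {}
        qc_raw = settings_raw.pop("qc_thresholds", {}) or {}
        thr_raw = settings_raw.pop("thresholds", {}) or {}
        settings = StudySettings(
            qc_thresholds=QCThresholds(**qc_raw),
            thresholds=ThresholdConfig(**thr_raw),
            **settings_raw,
        )
        return cls(settings=settings, **raw)


def load_inputs(config: StudyConfig) -> StudyInputs:
    for name in ("beta", "bead_count", "detection_p", "signal_zero", "sample_sheet",
                 "cell_counts", "components", "annotation"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise ValidationError(f"input path for {name!r} does not exist: {path}")
    cross_reactive: set[str] = set()
    if config.cross_reactive:
        with open(config.cross_reactive) as handle:
            cross_reactive = {line.strip() for line in handle if line.strip()}
    gene_sets = read_gmt(config.gmt) if config.gmt else None
    return StudyInputs(
        beta=read_beta_matrix(config.beta),
        qc_metrics=read_qc_metrics(config.bead_count, config.detection_p, config.signal_zero),
        sample_sheet=read_sample_sheet(config.sample_sheet),
        cell_counts=read_cell_counts(config.cell_counts),
        components=read_components(config.components),
        annotation=read_annotation(config.annotation),
        cross_reactive=cross_reactive,
        gene_sets=gene_sets,
    )


def run_full_study(config: StudyConfig) -> StudyResult:
    """Load the configured inputs and write the full report bundle."""
    inputs = load_inputs(config)
    return run_study(inputs, config.settings, output_dir=config.output_dir)
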