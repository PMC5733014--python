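"""Synthetic MZ-twin cohort generator with planted ground truth.

The generator emulates the statistical structure every pipeline stage
assumes: per-probe methylation decomposes into a bimodal baseline, a
pair-shared deviate (variance ``sigma_pair_sq``) and an individual deviate
(``sigma_indiv_sq``), plus optional leukocyte-composition loadings; the six
cognitive components at intake arise from a pair-shared general factor
(composite intraclass correlation = ``cognition_pair_icc``), an individual
general factor and component-specific noise; follow-up components equal the
intake components plus one sixth of an individual 10-year change score
(mean ``decline_mean``, SD ``decline_sd``, half of its variance pair-shared).
Chip positions are assigned cyclically; bead/detection/zero-signal failures,
high-missingness probes and cross-reactive probes are planted at configured
rates; a configurable number of samples lack cell counts.

Planted associations: for causal probes the M-value additionally contains
``effect_size_m_per_unit`` times the individual's composite (cross-sectional
targets) or change score (longitudinal targets), the composite being
computed with the package's own phenotype functions so that the planted
slope is exactly the estimand of every downstream scan. The truth table
records target and effect per probe.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` child streams (demographics, cognition,
cells, methylation, qc, annotation), so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phenotype as phen
from .data_model import (
    CELL_TYPES,
    Annotation,
    BetaMatrix,
    CellCounts,
    GeneSetCollection,
    ProbeQCMetrics,
    SampleSheet,
    ValidationError,
    read_annotation,
    read_beta_matrix,
    read_cell_counts,
    read_qc_metrics,
    read_sample_sheet,
    write_annotation,
    write_beta_matrix,
    write_cell_counts,
    write_qc_metrics,
    write_sample_sheet,
)

_STREAMS = ["demographics", "cognition", "cells", "methylation", "qc", "annotation"]

# raw score scales for the six components (means/SDs on test-native units;
# the pipeline's standardization absorbs them)
_COMPONENT_MEANS = np.array([45.0, 7.0, 6.0, 40.0, 35.0, 5.0])
_COMPONENT_SDS = np.array([11.0, 2.2, 2.0, 10.0, 12.0, 1.8])

# typical leukocyte counts, 10^9 cells/L
_TYPICAL_COUNTS = np.array([0.5, 2.1, 0.05, 3.8, 0.15])

_GENERAL_FACTOR_SHARE = 0.5  # share of each component's variance from g/f factors


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort the pipeline was designed around: 243
    complete MZ pairs (111 female, 132 male), ages 55–79 at follow-up,
    nine samples without measured cell counts, a ten-year mean composite
    decline of −1.64 units, and ~6% cross-reactive probes.
    """

    seed: int = 0
    n_pairs: int = 243
    n_probes: int = 20000
    n_causal_cross_sectional: int = 5
    n_causal_longitudinal: int = 5
    effect_size_m_per_unit: float = 0.03
    sigma_pair_sq: float = 0.12
    sigma_indiv_sq: float = 0.12
    cognition_pair_icc: float = 0.5
    cell_effect_scale: float = 0.05
    cell_assoc_fraction: float = 0.2
    missing_cell_samples: int = 9
    qc_failure_rates: tuple[float, float, float] = (0.001, 0.001, 0.0005)
    n_cross_reactive: int | None = None
    n_high_missing_probes: int = 0
    age_range: tuple[float, float] = (55.0, 79.0)
    female_pair_fraction: float = 111.0 / 243.0
    incomplete_pair_fraction: float = 0.0
    decline_mean: float = -1.64
    decline_sd: float = 3.0

    def __post_init__(self) -> None:
        if min(self.sigma_pair_sq, self.sigma_indiv_sq) < 0:
            raise ValidationError("variance components must be >= 0")
        for frac in (
            self.cognition_pair_icc,
            self.cell_assoc_fraction,
            self.female_pair_fraction,
            self.incomplete_pair_fraction,
            *self.qc_failure_rates,
        ):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions and rates must lie in [0, 1]")
        if self.n_causal_cross_sectional + self.n_causal_longitudinal > self.n_probes:
            raise ValidationError("more causal probes requested than probes simulated")
        max_icc = 36.0 * _GENERAL_FACTOR_SHARE / (30.0 * _GENERAL_FACTOR_SHARE + 6.0)
        if self.cognition_pair_icc > max_icc:
            raise ValidationError(f"cognition_pair_icc must be <= {max_icc:.3f}")
        if self.missing_cell_samples > self.n_samples:
            raise ValidationError("missing_cell_samples exceeds the number of samples")

    @property
    def n_samples(self) -> int:
        n_incomplete = round(self.incomplete_pair_fraction * self.n_pairs)
        return 2 * self.n_pairs - n_incomplete

    def resolved_n_cross_reactive(self) -> int:
        if self.n_cross_reactive is not None:
            return self.n_cross_reactive
        return round(0.06 * self.n_probes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key in ("qc_failure_rates", "age_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


PRESETS: dict[str, SimulationConfig] = {
    "demo": SimulationConfig(
        n_pairs=20,
        n_probes=500,
        n_causal_cross_sectional=2,
        n_causal_longitudinal=2,
        missing_cell_samples=4,
        n_cross_reactive=10,
        n_high_missing_probes=3,
    ),
    "paper-scale": SimulationConfig(),
}


@dataclass
class SimulatedCohort:
    """Everything one pipeline run needs, plus the planted ground truth."""

    config: SimulationConfig
    beta: BetaMatrix
    qc_metrics: ProbeQCMetrics
    sample_sheet: SampleSheet
    cell_counts: CellCounts
    components: phen.CognitiveComponents
    cross_reactive: set[str]
    annotation: Annotation
    truth: pd.DataFrame = field(repr=False)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    rngs = _streams(config.seed)

    # --- demographics -----------------------------------------------------
    rng = rngs["demographics"]
    n_pairs = config.n_pairs
    pair_ids = [f"P{i:04d}" for i in range(n_pairs)]
    n_female = round(config.female_pair_fraction * n_pairs)
    pair_sex = np.array(["female"] * n_female + ["male"] * (n_pairs - n_female))
    rng.shuffle(pair_sex)
    pair_age = rng.uniform(*config.age_range, size=n_pairs).round(1)
    n_incomplete = round(config.incomplete_pair_fraction * n_pairs)
    incomplete = set(rng.choice(n_pairs, size=n_incomplete, replace=False).tolist())

    rows = []
    sample_pair_idx = []
    for j, pid in enumerate(pair_ids):
        members = ["A"] if j in incomplete else ["A", "B"]
        for member in members:
            rows.append(
                {
                    "sample_id": f"{pid}{member}",
                    "pair_id": pid,
                    "sex": pair_sex[j],
                    "age_followup": pair_age[j],
                }
            )
            sample_pair_idx.append(j)
    sheet = pd.DataFrame(rows)
    n_samples = len(sheet)
    idx = np.arange(n_samples)
    sheet["chip_side"] = np.where((idx // 6) % 2 == 0, "Left", "Right")
    sheet["chip_row"] = idx % 6 + 1
    sample_sheet = SampleSheet(sheet)
    sample_ids = sheet["sample_id"].tolist()
    pair_of_sample = np.array(sample_pair_idx)

    # --- cognition --------------------------------------------------------
    rng = rngs["cognition"]
    h = _GENERAL_FACTOR_SHARE
    a2 = (30.0 * h + 6.0) * config.cognition_pair_icc / 36.0
    b2 = h - a2
    c2 = 1.0 - h
    g = rng.normal(size=n_pairs)[pair_of_sample]  # pair-shared general factor
    f = rng.normal(size=n_samples)  # individual general factor
    e = rng.normal(size=(n_samples, 6))
    latent_intake = (
        np.sqrt(a2) * g[:, None] + np.sqrt(b2) * f[:, None] + np.sqrt(c2) * e
    )
    q = rng.normal(size=n_pairs)[pair_of_sample]
    w = rng.normal(size=n_samples)
    change = config.decline_mean + config.decline_sd * (
        np.sqrt(0.5) * q + np.sqrt(0.5) * w
    )
    latent_follow = latent_intake + change[:, None] / 6.0
    raw_intake = _COMPONENT_MEANS + _COMPONENT_SDS * latent_intake
    raw_follow = _COMPONENT_MEANS + _COMPONENT_SDS * latent_follow
    comp_rows = []
    for wave, raw in (("intake", raw_intake), ("followup", raw_follow)):
        frame = pd.DataFrame(raw, columns=phen.COMPONENTS)
        frame.insert(0, "wave", wave)
        frame.insert(0, "sample_id", sample_ids)
        comp_rows.append(frame)
    components = phen.CognitiveComponents(pd.concat(comp_rows, ignore_index=True))

    # composites as the pipeline computes them — the causal slopes below are
    # planted against exactly this scale
    composites, _ = phen.compute_composites(components, reference_wave="intake")
    followup_composite = (
        composites[composites["wave"] == "followup"].set_index("sample_id")["value"]
    )
    intake_composite = (
        composites[composites["wave"] == "intake"].set_index("sample_id")["value"]
    )
    change_score = (followup_composite - intake_composite).reindex(sample_ids)
    followup_composite = followup_composite.reindex(sample_ids)

    # --- cell counts ------------------------------------------------------
    rng = rngs["cells"]
    pair_dev = rng.normal(scale=0.15, size=(n_pairs, 5))[pair_of_sample]
    indiv_dev = rng.normal(scale=0.20, size=(n_samples, 5))
    true_counts = np.exp(np.log(_TYPICAL_COUNTS) + pair_dev + indiv_dev)
    zlog = np.log1p(true_counts)
    zlog = (zlog - zlog.mean(axis=0)) / zlog.std(axis=0)
    missing_cells = rng.choice(n_samples, size=config.missing_cell_samples, replace=False)
    counts_frame = pd.DataFrame(true_counts.copy(), columns=CELL_TYPES)
    counts_frame.insert(0, "sample_id", sample_ids)
    counts_frame.loc[missing_cells, CELL_TYPES] = np.nan
    cell_counts = CellCounts(counts_frame)

    # --- methylation ------------------------------------------------------
    rng = rngs["methylation"]
    n_probes = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    mode = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    mu = np.where(
        mode == 0,
        rng.normal(-2.5, 0.8, size=n_probes),
        np.where(mode == 1, rng.normal(2.5, 0.8, size=n_probes), rng.normal(0.0, 1.0, size=n_probes)),
    )
    u = rng.normal(scale=np.sqrt(config.sigma_pair_sq), size=(n_probes, n_pairs))
    eps = rng.normal(scale=np.sqrt(config.sigma_indiv_sq), size=(n_probes, n_samples))
    M = mu[:, None] + u[:, pair_of_sample] + eps

    cell_assoc = rng.random(n_probes) < config.cell_assoc_fraction
    loadings = np.zeros((n_probes, 5))
    loadings[cell_assoc] = rng.normal(
        scale=config.cell_effect_scale, size=(int(cell_assoc.sum()), 5)
    )
    M += loadings @ zlog.T

    n_cs = config.n_causal_cross_sectional
    n_long = config.n_causal_longitudinal
    causal = rng.choice(n_probes, size=n_cs + n_long, replace=False)
    cs_idx, long_idx = causal[:n_cs], causal[n_cs:]
    cell_assoc[causal] = False
    loadings[causal] = 0.0
    beta_effect = config.effect_size_m_per_unit
    M[cs_idx] += beta_effect * np.nan_to_num(followup_composite.to_numpy())
    M[long_idx] += beta_effect * np.nan_to_num(change_score.to_numpy())

    beta_values = 1.0 / (1.0 + np.exp2(-M))
    beta = BetaMatrix(pd.DataFrame(beta_values, index=probe_ids, columns=sample_ids))

    target = np.array(["none"] * n_probes, dtype=object)
    target[cs_idx] = "cross-sectional"
    target[long_idx] = "longitudinal"
    effect = np.zeros(n_probes)
    effect[causal] = beta_effect
    truth = pd.DataFrame(
        {"probe_id": probe_ids, "target": target, "true_effect": effect, "cell_assoc": cell_assoc}
    )

    # --- QC metrics -------------------------------------------------------
    rng = rngs["qc"]
    bead_rate, det_rate, zero_rate = config.qc_failure_rates
    bead = rng.poisson(12, size=(n_probes, n_samples)) + 3
    detection = rng.uniform(0.0, 0.005, size=(n_probes, n_samples))
    bead_fail = rng.random((n_probes, n_samples)) < bead_rate
    bead[bead_fail] = 2
    det_fail = rng.random((n_probes, n_samples)) < det_rate
    detection[det_fail] = rng.uniform(0.011, 0.05, size=int(det_fail.sum()))
    signal_zero = rng.random((n_probes, n_samples)) < zero_rate

    eligible = np.flatnonzero(target == "none")
    high_missing = rng.choice(eligible, size=config.n_high_missing_probes, replace=False)
    n_fail = int(0.05 * n_samples) + 2  # strictly above the 5% missingness cutoff
    for p in high_missing:
        cols = rng.choice(n_samples, size=n_fail, replace=False)
        detection[p, cols] = 0.02
    qc_metrics = ProbeQCMetrics(
        bead_count=pd.DataFrame(bead, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(detection, index=probe_ids, columns=sample_ids),
        signal_zero=pd.DataFrame(signal_zero, index=probe_ids, columns=sample_ids),
    )
    cr_eligible = np.setdiff1d(eligible, high_missing)
    n_cr = config.resolved_n_cross_reactive()
    cross_reactive = {
        probe_ids[i] for i in rng.choice(cr_eligible, size=n_cr, replace=False)
    }

    annotation = _simulate_annotation(probe_ids, rngs["annotation"])

    return SimulatedCohort(
        config=config,
        beta=beta,
        qc_metrics=qc_metrics,
        sample_sheet=sample_sheet,
        cell_counts=cell_counts,
        components=components,
        cross_reactive=cross_reactive,
        annotation=annotation,
        truth=truth,
    )


def _simulate_annotation(probe_ids: list[str], rng: np.random.Generator) -> Annotation:
    """Manifest-like annotation: contiguous probe blocks share a gene, genes
    share a chromosome; ~55% of probes fall inside their gene (distance NA)."""
    n_probes = len(probe_ids)
    n_genes = max(10, n_probes // 3)
    gene_idx = (np.arange(n_probes) * n_genes) // n_probes
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])[gene_idx]
    chrom_idx = (np.arange(n_probes) * 22) // n_probes + 1
    position = np.zeros(n_probes, dtype=int)
    for chrom in range(1, 23):
        mask = chrom_idx == chrom
        steps = rng.integers(500, 5000, size=int(mask.sum()))
        position[mask] = 10_000 + np.cumsum(steps)
    inside = rng.random(n_probes) < 0.55
    regions = np.where(
        inside,
        rng.choice(["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"], size=n_probes),
        "IGR",
    )
    distance = np.where(
        inside,
        0,
        rng.integers(1_000, 200_000, size=n_probes) * rng.choice([-1, 1], size=n_probes),
    )
    context = rng.choice(["island", "shore", "shelf", "open sea"], size=n_probes, p=[0.3, 0.25, 0.1, 0.35])
    frame = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom_idx.astype(str),
            "position": position,
            "gene_symbol": genes,
            "distance_bp": pd.array(distance, dtype="Int64"),
            "cgi_feature": [f"{r}-{c}" for r, c in zip(regions, context)],
        }
    )
    frame.loc[inside, "distance_bp"] = pd.NA
    return Annotation(frame)


def random_gene_sets(
    annotation: Annotation,
    n_sets: int = 20,
    size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
    source: str = "simulated",
) -> GeneSetCollection:
    """Random gene sets drawn from the annotation's universe (for exercising
    the ORA stage when no curated GMT is supplied)."""
    rng = np.random.default_rng(seed)
    universe = sorted(annotation.gene_universe())
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i:03d}"] = set(members.tolist())
    return GeneSetCollection(sets, source=source)


# ---------------------------------------------------------------------------
# persistence

_FILES = {
    "beta": "beta.tsv",
    "bead_count": "bead_count.tsv",
    "detection_p": "detection_p.tsv",
    "signal_zero": "signal_zero.tsv",
    "sample_sheet": "sample_sheet.tsv",
    "cell_counts": "cell_counts.tsv",
    "components": "components.tsv",
    "cross_reactive": "cross_reactive.txt",
    "annotation": "annotation.tsv",
    "truth": "truth.tsv",
}


def write_cohort(cohort: SimulatedCohort, directory) -> dict[str, str]:
    """Write every cohort table in the pipeline's TSV dialect plus a
    manifest recording the exact configuration and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(cohort.beta, directory / _FILES["beta"])
    write_qc_metrics(
        cohort.qc_metrics,
        directory / _FILES["bead_count"],
        directory / _FILES["detection_p"],
        directory / _FILES["signal_zero"],
    )
    write_sample_sheet(cohort.sample_sheet, directory / _FILES["sample_sheet"])
    write_cell_counts(cohort.cell_counts, directory / _FILES["cell_counts"])
    phen.write_components(cohort.components, directory / _FILES["components"])
    with open(directory / _FILES["cross_reactive"], "w") as handle:
        handle.write("\n".join(sorted(cohort.cross_reactive)) + "\n")
    write_annotation(cohort.annotation, directory / _FILES["annotation"])
    truth = cohort.truth.copy()
    truth["cell_assoc"] = truth["cell_assoc"].astype(int)
    truth.to_csv(directory / _FILES["truth"], sep="\t", index=False, na_rep="NA")
    manifest = {
        "files": dict(_FILES),
        "config": cohort.config.to_dict(),
        "seed": cohort.config.seed,
    }
    with open(directory / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return dict(_FILES)


def read_cohort(directory) -> SimulatedCohort:
    """Load a cohort previously written with :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as handle:
        manifest = json.load(handle)
    config = SimulationConfig.from_dict(manifest["config"])
    with open(directory / _FILES["cross_reactive"]) as handle:
        cross_reactive = {line.strip() for line in handle if line.strip()}
    truth = pd.read_csv(directory / _FILES["truth"], sep="\t", na_values=["NA"], keep_default_na=False)
    truth["cell_assoc"] = truth["cell_assoc"].astype(bool)
    return SimulatedCohort(
        config=config,
        beta=read_beta_matrix(directory / _FILES["beta"]),
        qc_metrics=read_qc_metrics(
            directory / _FILES["bead_count"],
            directory / _FILES["detection_p"],
            directory / _FILES["signal_zero"],
        ),
        sample_sheet=read_sample_sheet(directory / _FILES["sample_sheet"]),
        cell_counts=read_cell_counts(directory / _FILES["cell_counts"]),
        components=phen.read_components(directory / _FILES["components"]),
        cross_reactive=cross_reactive,
        annotation=read_annotation(directory / _FILES["annotation"]),
        truth=truth,
    )
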