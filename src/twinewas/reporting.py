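"""Multiple testing, thresholds, annotation joins, overlaps, Manhattan tables.

Probe-level results are reported against fixed thresholds (suggestive
p < 1e-5, significant p < 1e-6, cross-analysis overlap at p < 1e-4) rather
than FDR-corrected; Benjamini-Hochberg is provided as a utility taking an
explicit family size so that truncated p-value lists are never silently
corrected against the wrong m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Annotation, ValidationError

logger = logging.getLogger(__name__)

ANNOTATED_COLUMNS = [
    "probe_id",
    "estimate",
    "standard_error",
    "p_value",
    "chromosome",
    "position",
    "gene_symbol",
    "distance_bp",
    "cgi_feature",
]


@dataclass(frozen=True)
class ThresholdConfig:
    suggestive_p: float = 1e-5
    significant_p: float = 1e-6
    overlap_p: float = 1e-4

    def __post_init__(self) -> None:
        if not self.significant_p <= self.suggestive_p <= self.overlap_p:
            raise ValidationError("thresholds must satisfy significant <= suggestive <= overlap")


def benjamini_hochberg(p_values, m_total: int | None = None) -> np.ndarray:
    """BH step-up adjusted p-values, in input order.

    ``m_total`` is the total number of tests in the family; it may exceed
    the length of ``p_values`` when only the smallest p-values of a family
    are listed (the unlisted ones are then assumed larger than every listed
    one, which leaves the listed adjustments valid). adj_(i) =
    min_{j >= i} p_(j) * m_total / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must be in (0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValidationError(f"m_total ({m}) smaller than number of p-values ({len(p)})")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    scaled = p[order] * m / ranks
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def annotate_probes(results: pd.DataFrame, annotation: Annotation) -> pd.DataFrame:
    """Left-join gene/position/CGI annotation onto an EWAS result table.

    Estimates, SEs and p-values are never altered; probes absent from the
    annotation keep missing annotation fields and are logged.
    """
    ann = annotation.by_probe()[["chromosome", "position", "gene_symbol", "distance_bp", "cgi_feature"]]
    merged = results.merge(ann, left_on="probe_id", right_index=True, how="left")
    unannotated = merged.loc[merged["chromosome"].isna(), "probe_id"]
    for probe in unannotated:
        logger.warning("probe %s has no annotation record", probe)
    extra = [c for c in merged.columns if c not in ANNOTATED_COLUMNS]
    return merged[[c for c in ANNOTATED_COLUMNS if c in merged.columns] + extra]


def threshold_report(
    results: pd.DataFrame, thresholds: ThresholdConfig = ThresholdConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(suggestive, significant) tables under strict < cutoffs, sorted by
    ascending p (ties broken by probe id)."""
    ordered = results.sort_values(["p_value", "probe_id"], kind="stable")
    suggestive = ordered[ordered["p_value"] < thresholds.suggestive_p].reset_index(drop=True)
    significant = ordered[ordered["p_value"] < thresholds.significant_p].reset_index(drop=True)
    return suggestive, significant


@dataclass
class OverlapResult:
    """Pairwise intersections of hits (p < overlap_p) across analyses."""

    probe_overlap: dict[tuple[str, str], set[str]]
    gene_overlap: dict[tuple[str, str], set[str]]
    hit_probes: dict[str, set[str]]
    hit_genes: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.probe_overlap:
            rows.append(
                {
                    "analysis_1": key[0],
                    "analysis_2": key[1],
                    "shared_probes": ";".join(sorted(self.probe_overlap[key])) or None,
                    "n_shared_probes": len(self.probe_overlap[key]),
                    "shared_genes": ";".join(sorted(self.gene_overlap[key])) or None,
                    "n_shared_genes": len(self.gene_overlap[key]),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "analysis_1",
                "analysis_2",
                "shared_probes",
                "n_shared_probes",
                "shared_genes",
                "n_shared_genes",
            ],
        )


def overlap_analysis(
    result_tables: dict[str, pd.DataFrame],
    annotation: Annotation,
    overlap_p: float = 1e-4,
) -> OverlapResult:
    """Probe- and gene-level intersections among sub-threshold hits.

    A probe (gene) is shared between two analyses only if it passes
    p < overlap_p in both. Gene overlap uses the annotated nearest gene, so
    two analyses can share a gene through different probes.
    """
    if len(result_tables) < 2:
        raise ValidationError("overlap analysis needs at least two result tables")
    gene_of = annotation.by_probe()["gene_symbol"]
    hit_probes: dict[str, set[str]] = {}
    hit_genes: dict[str, set[str]] = {}
    for name, table in result_tables.items():
        hits = table.loc[table["p_value"] < overlap_p, "probe_id"]
        hit_probes[name] = set(hits)
        hit_genes[name] = set(gene_of.reindex(hits).dropna())
    names = sorted(result_tables)
    probe_overlap, gene_overlap = {}, {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            probe_overlap[(a, b)] = hit_probes[a] & hit_probes[b]
            gene_overlap[(a, b)] = hit_genes[a] & hit_genes[b]
    return OverlapResult(probe_overlap, gene_overlap, hit_probes, hit_genes)


CHROMOSOME_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def manhattan_table(annotated_results: pd.DataFrame, label_p: float = 1e-6) -> pd.DataFrame:
    """Plot-ready table: chromosome, cumulative coordinate, −log10 p, label flag.

    Probes are ordered by (chromosome, position); the cumulative coordinate
    offsets each chromosome by the maximum position of its predecessors.
    """
    table = annotated_results.dropna(subset=["chromosome", "position", "p_value"]).copy()
    table["chromosome"] = table["chromosome"].astype(str)
    table["_chrom_rank"] = table["chromosome"].map(CHROMOSOME_ORDER)
    if table["_chrom_rank"].isna().any():
        bad = table.loc[table["_chrom_rank"].isna(), "chromosome"].iloc[0]
        raise ValidationError(f"unknown chromosome {bad!r}")
    table = table.sort_values(["_chrom_rank", "position"], kind="stable")
    offsets, offset = {}, 0
    for chrom, grp in table.groupby("_chrom_rank", sort=True):
        offsets[chrom] = offset
        offset += int(grp["position"].max())
    table["cumulative_position"] = table["position"].astype(int) + table["_chrom_rank"].map(offsets)
    table["neg_log10_p"] = -np.log10(table["p_value"].astype(float))
    table["label"] = table["p_value"] < label_p
    out = table[
        ["probe_id", "chromosome", "position", "cumulative_position", "neg_log10_p", "label", "gene_symbol"]
    ].reset_index(drop=True)
    return out


def manhattan_plot(table: pd.DataFrame, path, title: str = "") -> None:
    """Render a Manhattan plot from :func:`manhattan_table` output (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, (_, grp) in enumerate(table.groupby("chromosome", sort=False)):
        ax.scatter(grp["cumulative_position"], grp["neg_log10_p"], s=4,
                   color="#4c72b0" if i % 2 == 0 else "#9db8d9")
    for _, row in table[table["label"]].iterrows():
        ax.annotate(
            f"{row['probe_id']}\n{row['gene_symbol']}",
            (row["cumulative_position"], row["neg_log10_p"]),
            fontsize=6,
        )
    ax.axhline(6.0, color="red", lw=0.6, ls="--")
    ax.axhline(5.0, color="grey", lw=0.6, ls=":")
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
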