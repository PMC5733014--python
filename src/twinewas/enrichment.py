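"""Hypergeometric over-representation analysis of hit-gene lists.

The reference universe is the set of unique gene symbols on the (filtered)
array annotation. For each gene set the displayed statistics follow the
usual ORA conventions: C = genes of the set present in the universe,
O = observed overlap with the hit list, E = C·n/N the expected overlap
(n = hit genes in the universe, N = universe size), R = O/E the enrichment
ratio, and raw_p = P(X ≥ O) for X ~ Hypergeometric(N, C, n) — an upper-tail
(over-representation) test only. Raw p-values are BH-adjusted with family
size = number of sets actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Annotation, GeneSetCollection, ValidationError
from .reporting import benjamini_hochberg

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_name", "n_overlap_genes", "overlap_genes", "C", "O", "E", "R", "raw_p", "adj_p",
]


@dataclass(frozen=True)
class Reference:
    """Gene universe plus per-set membership restricted to it."""

    universe: frozenset[str]
    set_genes: dict[str, frozenset[str]]

    @property
    def n_genes(self) -> int:
        return len(self.universe)


def build_reference(
    annotation: Annotation, collection: GeneSetCollection, min_set_size: int = 1
) -> Reference:
    """Intersect every gene set with the array's gene universe; sets that end
    up smaller than ``min_set_size`` are dropped with a warning."""
    universe = frozenset(annotation.gene_universe())
    if not universe:
        raise ValidationError("annotation yields an empty gene universe")
    set_genes = {}
    for name, members in collection.sets.items():
        inter = frozenset(members & universe)
        if len(inter) < min_set_size:
            logger.warning("gene set %s has %d universe genes, dropped", name, len(inter))
            continue
        set_genes[name] = inter
    return Reference(universe=universe, set_genes=set_genes)


def hits_to_genes(results: pd.DataFrame, annotation: Annotation, p_cutoff: float = 1e-4) -> set[str]:
    """Unique nearest-gene symbols of probes with p < p_cutoff (strict),
    restricted to the annotation's gene universe."""
    gene_of = annotation.by_probe()["gene_symbol"]
    hits = results.loc[results["p_value"] < p_cutoff, "probe_id"]
    return set(gene_of.reindex(hits).dropna())


def hypergeometric_ora(
    hit_genes: set[str], set_genes: frozenset[str], universe: frozenset[str]
) -> dict:
    """One set's ORA record (without adj_p): C, O, E, R and the exact
    hypergeometric upper-tail probability P(X ≥ O)."""
    n = len(hit_genes & universe)
    C = len(set_genes)
    N = len(universe)
    if n > N or C > N:
        raise ValidationError("hit list or gene set larger than the universe")
    overlap = sorted(hit_genes & set_genes)
    O = len(overlap)
    E = C * n / N
    if E == 0 and O > 0:
        raise ValidationError("observed overlap with zero expectation — inconsistent inputs")
    R = O / E if E > 0 else np.nan
    raw_p = 1.0 if O == 0 else float(stats.hypergeom.sf(O - 1, N, C, n))
    raw_p = min(max(raw_p, np.finfo(float).tiny), 1.0)
    return {
        "n_overlap_genes": O,
        "overlap_genes": ";".join(overlap),
        "C": C,
        "O": O,
        "E": E,
        "R": R,
        "raw_p": raw_p,
    }


def enrich_all(
    hit_genes: set[str],
    collection: GeneSetCollection,
    annotation: Annotation,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """ORA over every gene set, BH-adjusted with m = number of sets tested
    (all sets surviving the universe intersection, before any display
    filtering); sorted by raw_p, ties by set name."""
    reference = build_reference(annotation, collection, min_set_size=min_set_size)
    if not hit_genes & reference.universe:
        logger.info("no hit genes in the reference universe; enrichment skipped")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    rows = []
    for name in sorted(reference.set_genes):
        record = hypergeometric_ora(hit_genes, reference.set_genes[name], reference.universe)
        record["set_name"] = name
        rows.append(record)
    table = pd.DataFrame(rows)
    table["adj_p"] = benjamini_hochberg(table["raw_p"].to_numpy(), m_total=len(table))
    table = table.sort_values(["raw_p", "set_name"], kind="stable").reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]
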