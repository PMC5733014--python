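"""Intra-pair difference association scan (the paired approach).

For every complete MZ pair the within-pair differences of M-values,
phenotype and cell counts are taken (minuend = lexicographically smaller
sample id, a deterministic but arbitrary orientation; the intercept absorbs
any orientation-dependent mean shift). Differencing removes all pair-shared
effects — genetic background and shared environment — so each probe is
tested by ordinary least squares of ΔM on Δphenotype with pair-level sex
and age and the five Δcell-count covariates. Inference is an exact t-test
with n_pairs − 8 degrees of freedom. A discordance-stratified variant keeps
the pairs with the largest |Δphenotype|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CELL_TYPES, CellCounts, SampleSheet, ValidationError
from .qc import MValueMatrix

logger = logging.getLogger(__name__)

COVARIATE_TERMS = ["intercept", "delta_phenotype", "sex", "age", *[f"delta_{c}" for c in CELL_TYPES]]
N_PARAMS = len(COVARIATE_TERMS)


@dataclass
class PairedDesign:
    """Per-pair differenced response and covariates.

    ``delta_m`` is pairs × probes; ``covariates`` holds delta_phenotype,
    sex (female = 1), age at follow-up and the five cell-count differences,
    indexed by pair id. ``orientation`` records (minuend, subtrahend) per
    pair; ``excluded`` logs pairs left out and why.
    """

    delta_m: pd.DataFrame
    covariates: pd.DataFrame
    orientation: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["pair_id", "reason"]))

    @property
    def n_pairs(self) -> int:
        return len(self.covariates)

    @property
    def pair_ids(self) -> pd.Index:
        return self.covariates.index


def build_pair_differences(
    mvalues: MValueMatrix,
    sample_sheet: SampleSheet,
    phenotype: pd.Series,
    cell_counts: CellCounts,
) -> PairedDesign:
    """Difference every complete pair; incomplete or unusable pairs are
    excluded with a reason (missing member, phenotype or cell counts)."""
    sheet = sample_sheet.data.set_index("sample_id")
    counts = cell_counts.counts_by_sample()
    pairs = sample_sheet.complete_pairs()
    excluded: list[dict] = []
    for pid in sample_sheet.incomplete_pair_ids():
        excluded.append({"pair_id": pid, "reason": "incomplete pair"})

    rows, orient, delta_cols = [], [], []
    for pair_id in sorted(pairs):
        a, b = pairs[pair_id]  # a < b lexicographically: a is the minuend
        if a not in mvalues.sample_ids or b not in mvalues.sample_ids:
            excluded.append({"pair_id": pair_id, "reason": "member missing methylation"})
            continue
        pa, pb = phenotype.get(a, np.nan), phenotype.get(b, np.nan)
        if pd.isna(pa) or pd.isna(pb):
            excluded.append({"pair_id": pair_id, "reason": "member missing phenotype"})
            continue
        if (
            a not in counts.index
            or b not in counts.index
            or counts.loc[[a, b]].isna().any().any()
        ):
            excluded.append({"pair_id": pair_id, "reason": "member missing cell counts"})
            continue
        row = {
            "delta_phenotype": float(pa) - float(pb),
            "sex": 1.0 if sheet.loc[a, "sex"] == "female" else 0.0,
            "age": float(sheet.loc[a, "age_followup"]),
        }
        for cell in CELL_TYPES:
            row[f"delta_{cell}"] = float(counts.loc[a, cell]) - float(counts.loc[b, cell])
        rows.append(row)
        orient.append({"pair_id": pair_id, "minuend": a, "subtrahend": b})
        delta_cols.append(pair_id)

    if not rows:
        raise ValidationError("no complete pairs available for the paired design")
    orientation = pd.DataFrame(orient).set_index("pair_id")
    covariates = pd.DataFrame(rows, index=orientation.index)
    minu = mvalues.data[orientation["minuend"]].to_numpy(dtype=float)
    subt = mvalues.data[orientation["subtrahend"]].to_numpy(dtype=float)
    delta_m = pd.DataFrame(
        (minu - subt).T, index=orientation.index, columns=mvalues.probe_ids
    )
    for entry in excluded:
        logger.info("pair %s excluded: %s", entry["pair_id"], entry["reason"])
    return PairedDesign(
        delta_m=delta_m,
        covariates=covariates,
        orientation=orientation,
        excluded=pd.DataFrame(excluded, columns=["pair_id", "reason"]),
    )


def select_most_discordant(design: PairedDesign, fraction: float = 0.5) -> PairedDesign:
    """Keep the ⌈fraction × n⌉ pairs with largest |Δphenotype| (ties by pair id)."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * design.n_pairs)
    ranking = design.covariates.assign(_abs=design.covariates["delta_phenotype"].abs())
    ranking = ranking.sort_values(["_abs", "pair_id"], ascending=[False, True], kind="stable")
    keep = ranking.index[:n_keep]
    return PairedDesign(
        delta_m=design.delta_m.loc[keep],
        covariates=design.covariates.loc[keep],
        orientation=design.orientation.loc[keep],
        excluded=design.excluded,
    )


def run_paired_ewas(
    design: PairedDesign,
    probe_ids=None,
    analysis: str = "paired-cognition",
) -> pd.DataFrame:
    """OLS of ΔM on Δphenotype + covariates, one fit per probe.

    Returns probe_id, estimate (coefficient on Δphenotype), standard error,
    two-sided t p-value (df = n_pairs − 8), n_units and the analysis label.
    Probes with missing differences are fitted on their complete pairs.
    """
    n = design.n_pairs
    if n < N_PARAMS + 1:
        raise ValidationError(f"need at least {N_PARAMS + 1} pairs, have {n}")
    X = np.column_stack(
        [np.ones(n), design.covariates[COVARIATE_TERMS[1:]].to_numpy(dtype=float)]
    )
    if np.ptp(X[:, 1]) == 0:
        logger.warning("delta_phenotype is constant; paired results unavailable")
        probes = design.delta_m.columns if probe_ids is None else pd.Index(probe_ids)
        return pd.DataFrame(
            {
                "probe_id": probes,
                "estimate": np.nan,
                "standard_error": np.nan,
                "p_value": np.nan,
                "n_units": n,
                "analysis": analysis,
            }
        )
    probes = design.delta_m.columns if probe_ids is None else pd.Index(probe_ids)
    Y = design.delta_m[probes].to_numpy(dtype=float)

    complete = ~np.isnan(Y).any(axis=0)
    est = np.full(len(probes), np.nan)
    se = np.full(len(probes), np.nan)
    pval = np.full(len(probes), np.nan)
    n_units = np.full(len(probes), n)

    if complete.any():
        est_c, se_c, p_c = _ols_block(X, Y[:, complete])
        est[complete], se[complete], pval[complete] = est_c, se_c, p_c
    for k in np.flatnonzero(~complete):
        mask = ~np.isnan(Y[:, k])
        n_units[k] = int(mask.sum())
        if n_units[k] < N_PARAMS + 1:
            logger.warning("probe %s: only %d complete pairs, skipped", probes[k], n_units[k])
            continue
        e, s, p = _ols_block(X[mask], Y[mask, k : k + 1])
        est[k], se[k], pval[k] = e[0], s[0], p[0]

    return pd.DataFrame(
        {
            "probe_id": probes,
            "estimate": est,
            "standard_error": se,
            "p_value": pval,
            "n_units": n_units,
            "analysis": analysis,
        }
    )


def _ols_block(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of each column of Y on X; returns the Δphenotype
    coefficient, its SE and the two-sided t p-value."""
    n, p = X.shape
    xtx = X.T @ X
    # pinv tolerates covariate columns that are identically zero (e.g. no
    # cell-count variation in a fixture); the phenotype column must vary.
    xtx_inv = np.linalg.pinv(xtx)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    est = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.inf * np.sign(est))
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return est, se, pval
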