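"""Imputation of missing leukocyte counts by partial least squares.

A multivariate PLS regression is fitted on the samples with measured
counts, with log(count + 1) for the five subtypes as the joint response and,
as predictors, every methylation probe observed in all samples plus sex,
age at follow-up and the chip-position dummies (side, row). Predictors are
centered and scaled with training statistics inside the PLS fit. The fitted
model predicts the missing samples; predictions are back-transformed with
exp(·) − 1 and floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .data_model import CELL_TYPES, BetaMatrix, CellCounts, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


def _covariate_frame(sheet: pd.DataFrame) -> pd.DataFrame:
    """Sex/age/chip-position covariates, chip position as two categoricals
    dummy-coded (side: Right vs Left; row: 2..6 vs 1)."""
    cov = pd.DataFrame(index=sheet.index)
    cov["sex_female"] = (sheet["sex"] == "female").astype(float)
    cov["age_followup"] = sheet["age_followup"].astype(float)
    cov["chip_side_Right"] = (sheet["chip_side"] == "Right").astype(float)
    for row in range(2, 7):
        cov[f"chip_row_{row}"] = (sheet["chip_row"].astype(int) == row).astype(float)
    return cov


@dataclass
class CellImputerModel:
    """Fitted PLS imputer plus the exact predictor list it requires."""

    pls: PLSRegression
    predictor_probes: list[str]
    covariate_names: list[str] = field(default_factory=list)
    n_components: int = 0
    n_training_samples: int = 0

    def predict_counts(self, predictors: pd.DataFrame) -> pd.DataFrame:
        """Counts on the natural scale: exp(PLS prediction) − 1, floored at 0."""
        log_pred = self.pls.predict(predictors.to_numpy(dtype=float))
        counts = np.maximum(np.expm1(log_pred), 0.0)
        return pd.DataFrame(counts, index=predictors.index, columns=CELL_TYPES)


def _build_predictors(
    beta: BetaMatrix, sample_sheet: SampleSheet, predictor_probes: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    sheet = sample_sheet.data.set_index("sample_id")
    samples = [s for s in beta.sample_ids if s in sheet.index]
    probes_frame = beta.data[samples]
    if predictor_probes is None:
        fully_observed = probes_frame.notna().all(axis=1)
        predictor_probes = list(probes_frame.index[fully_observed])
    else:
        missing = [p for p in predictor_probes if p not in probes_frame.index]
        if missing:
            raise ValidationError(f"sample set lacks predictor probe {missing[0]!r}")
        if probes_frame.loc[predictor_probes].isna().any().any():
            bad = probes_frame.loc[predictor_probes].isna().any(axis=1)
            raise ValidationError(
                f"predictor probe {bad.index[bad][0]!r} has missing values in prediction samples"
            )
    X = probes_frame.loc[predictor_probes].T
    cov = _covariate_frame(sheet.loc[samples])
    return pd.concat([X, cov], axis=1), predictor_probes


def fit_cell_imputer(
    beta: BetaMatrix,
    sample_sheet: SampleSheet,
    cell_counts: CellCounts,
    n_components: int = 10,
) -> CellImputerModel:
    """Fit the multivariate PLS on samples with complete measured counts."""
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    predictors, probes = _build_predictors(beta, sample_sheet)
    counts = cell_counts.counts_by_sample()
    train_samples = [
        s for s in predictors.index if s in counts.index and counts.loc[s].notna().all()
    ]
    if len(train_samples) < n_components + 1:
        raise ValidationError(
            f"{len(train_samples)} complete-count samples cannot support "
            f"{n_components} PLS components"
        )
    X = predictors.loc[train_samples]
    Y = np.log1p(counts.loc[train_samples].to_numpy(dtype=float))
    if n_components > min(X.shape):
        raise ValidationError("n_components exceeds the rank of the predictor matrix")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X.to_numpy(dtype=float), Y)
    return CellImputerModel(
        pls=pls,
        predictor_probes=probes,
        covariate_names=[c for c in predictors.columns if c not in probes],
        n_components=n_components,
        n_training_samples=len(train_samples),
    )


def choose_n_components_cv(
    beta: BetaMatrix,
    sample_sheet: SampleSheet,
    cell_counts: CellCounts,
    grid: tuple[int, ...] = (2, 5, 10, 15, 20),
    n_splits: int = 5,
    seed: int = 0,
) -> int:
    """Pick the component count minimising K-fold prediction error on the
    log scale over the training samples."""
    predictors, _ = _build_predictors(beta, sample_sheet)
    counts = cell_counts.counts_by_sample()
    train = [s for s in predictors.index if s in counts.index and counts.loc[s].notna().all()]
    X = predictors.loc[train].to_numpy(dtype=float)
    Y = np.log1p(counts.loc[train].to_numpy(dtype=float))
    best, best_err = None, np.inf
    for k in grid:
        if k > min(len(train) * (n_splits - 1) // n_splits, X.shape[1]):
            continue
        err = 0.0
        for tr, te in KFold(n_splits, shuffle=True, random_state=seed).split(X):
            pls = PLSRegression(n_components=k, scale=True)
            pls.fit(X[tr], Y[tr])
            err += float(((pls.predict(X[te]) - Y[te]) ** 2).mean())
        if err < best_err:
            best, best_err = k, err
    if best is None:
        raise ValidationError("no feasible component count in the grid")
    return best


def impute_missing_counts(
    model: CellImputerModel,
    beta: BetaMatrix,
    sample_sheet: SampleSheet,
    cell_counts: CellCounts,
) -> CellCounts:
    """Return counts for all samples: measured rows untouched, missing rows
    predicted and flagged ``imputed``."""
    counts = cell_counts.counts_by_sample()
    all_samples = pd.Index(sample_sheet.data["sample_id"])
    complete = counts.reindex(all_samples).notna().all(axis=1)
    missing_samples = list(all_samples[~complete])
    out = counts.reindex(all_samples).copy()
    imputed = pd.Series(False, index=all_samples)
    if missing_samples:
        subset = BetaMatrix(beta.data[[s for s in beta.sample_ids if s in missing_samples]])
        sheet = SampleSheet(
            sample_sheet.data[sample_sheet.data["sample_id"].isin(missing_samples)]
        )
        predictors, _ = _build_predictors(subset, sheet, model.predictor_probes)
        predicted = model.predict_counts(predictors)
        out.loc[predicted.index] = predicted
        imputed.loc[predicted.index] = True
        logger.info("imputed cell counts for %d samples", len(predicted))
    result = out.reset_index().rename(columns={"index": "sample_id"})
    result["imputed"] = imputed.to_numpy()
    return CellCounts(result)
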