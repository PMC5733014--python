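"""Cognitive composite scores, 10-year change, and the cohort decline test.

The composite is the sum of six brief cognitive test z-scores (verbal
fluency, immediate recall, delayed recall, processing speed, attention,
working memory). Standardization parameters (per-component mean and SD) are
estimated once on a reference wave — intake by default — and reused at both
waves so the two composites are commeasurable. At most one component may be
missing; a five-component composite is prorated by 6/5, and with two or more
missing the score is recorded as unavailable. The change score is follow-up
minus intake. Cohort-level decline is tested with an intercept-only
random-intercept model (pair as random effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SampleSheet, ValidationError, _read_tsv, _write_tsv
from .unpaired import fit_lmm

COMPONENTS = [
    "verbal_fluency",
    "immediate_recall",
    "delayed_recall",
    "processing_speed",
    "attention",
    "working_memory",
]
WAVES = ["intake", "followup"]


@dataclass
class CognitiveComponents:
    """Six test scores per sample and wave; any component may be missing."""

    data: pd.DataFrame  # columns: sample_id, wave, COMPONENTS

    def __post_init__(self) -> None:
        required = ["sample_id", "wave", *COMPONENTS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cognitive components missing columns: {missing}")
        if not self.data["wave"].isin(WAVES).all():
            raise ValidationError(f"wave must be one of {WAVES}")
        if self.data.duplicated(["sample_id", "wave"]).any():
            raise ValidationError("duplicate (sample_id, wave) rows")
        self.data = self.data.reset_index(drop=True)

    def at_wave(self, wave: str) -> pd.DataFrame:
        return self.data[self.data["wave"] == wave].set_index("sample_id")[COMPONENTS]


def read_components(path) -> CognitiveComponents:
    return CognitiveComponents(_read_tsv(path, dtype={"sample_id": str, "wave": str}))


def write_components(components: CognitiveComponents, path) -> None:
    _write_tsv(components.data[["sample_id", "wave", *COMPONENTS]], path)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-component mean/SD from the reference wave (SD is the n−1 sample SD)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0][0]
            raise ValidationError(f"component {bad!r} has non-positive SD")


def estimate_standardization(components: pd.DataFrame) -> StandardizationParams:
    """Mean/SD per component over the non-missing reference-wave values."""
    counts = components[COMPONENTS].notna().sum()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValidationError(f"component {bad!r} has fewer than 2 observations")
    mean = components[COMPONENTS].mean()
    sd = components[COMPONENTS].std(ddof=1)
    return StandardizationParams(mean=mean, sd=sd)


def compute_composite(
    components: pd.DataFrame, params: StandardizationParams, wave: str
) -> pd.DataFrame:
    """Composite score per sample: sum of z-scores, prorated by 6/5 when
    exactly one component is missing, unavailable when two or more are.

    ``components`` is indexed by sample_id with the six component columns.
    Returns columns: wave, value, n_components_used, available.
    """
    z = (components[COMPONENTS] - params.mean) / params.sd
    n_used = z.notna().sum(axis=1)
    provisional = z.sum(axis=1, min_count=1)
    value = provisional.where(n_used == 6, provisional * 6.0 / 5.0)
    available = n_used >= 5
    value[~available] = np.nan
    return pd.DataFrame(
        {
            "wave": wave,
            "value": value,
            "n_components_used": n_used,
            "available": available,
        },
        index=components.index,
    )


def compute_composites(
    components: CognitiveComponents, reference_wave: str = "intake"
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Composites at both waves with shared reference-wave standardization."""
    params = estimate_standardization(components.at_wave(reference_wave))
    frames = [compute_composite(components.at_wave(w), params, w) for w in WAVES]
    out = pd.concat(frames).rename_axis("sample_id").reset_index()
    return out, params


def compute_change(intake: pd.DataFrame, followup: pd.DataFrame) -> pd.DataFrame:
    """Change score = follow-up composite − intake composite, per sample.

    Both inputs are indexed by sample_id with ``value``/``available``
    columns; the index sets must match. Unavailable whenever either wave is.
    """
    if not intake.index.sort_values().equals(followup.index.sort_values()):
        raise ValidationError("intake and follow-up composites cover different samples")
    followup = followup.reindex(intake.index)
    available = intake["available"] & followup["available"]
    value = (followup["value"] - intake["value"]).where(available)
    return pd.DataFrame({"value": value, "available": available}, index=intake.index)


@dataclass(frozen=True)
class DeclineTestResult:
    mean_change: float
    standard_error: float
    p_value: float
    n_individuals: int
    n_pairs: int


def test_cohort_decline(change: pd.DataFrame, sample_sheet: SampleSheet) -> DeclineTestResult:
    """Wald test of zero mean change, with a pair random intercept.

    Fits the intercept-only random-intercept model to available change
    scores by REML and tests intercept = 0 with t on n − 1 degrees of
    freedom (approximate; the random-intercept fit already discounts the
    pair-shared variance).
    """
    sheet = sample_sheet.data.set_index("sample_id")
    values = change.loc[change["available"].fillna(False).astype(bool), "value"].dropna()
    values = values[values.index.isin(sheet.index)]
    if len(values) < 4 or sheet.loc[values.index, "pair_id"].nunique() < 2:
        raise ValidationError("decline test needs change scores from at least 2 pairs")
    y = values.to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    pairs = sheet.loc[values.index, "pair_id"].to_numpy()
    fit = fit_lmm(y, X, pairs, term_names=("intercept",), df=len(y) - 1)
    return DeclineTestResult(
        mean_change=float(fit.coef[0]),
        standard_error=float(fit.se[0]),
        p_value=fit.wald_p("intercept"),
        n_individuals=len(y),
        n_pairs=int(sheet.loc[values.index, "pair_id"].nunique()),
    )
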