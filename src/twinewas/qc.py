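"""Probe-level quality control and the beta → M-value transform.

Filtering runs in three stages: individual measurements failing bead-count,
detection-p or zero-signal checks are masked to missing; probes missing in
more than ``max_probe_missing_fraction`` of samples are then dropped; finally
any surviving probe on a supplied cross-reactive list is removed. Surviving
values are never altered. The retained beta values are mapped to M-values,
log2(b / (1 − b)), after clipping into [ε, 1 − ε] so fully (un)methylated
probes stay finite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, ProbeQCMetrics, ValidationError, _write_tsv

logger = logging.getLogger(__name__)

MASK_REASONS = ["bead", "detection", "zero-signal"]
DROP_REASONS = ["missingness", "cross-reactive"]


@dataclass(frozen=True)
class QCThresholds:
    """Measurement- and probe-level QC cutoffs.

    A measurement fails when bead_count < min_bead_count (strict), when
    detection_p > max_detection_p (strict — p exactly at the cutoff is
    retained), or when its signal is zero. A probe is dropped when its
    post-masking missing fraction exceeds max_probe_missing_fraction.
    """

    min_bead_count: int = 3
    max_detection_p: float = 0.01
    max_probe_missing_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_bead_count < 1:
            raise ValidationError("min_bead_count must be >= 1")
        if not 0 < self.max_detection_p < 1:
            raise ValidationError("max_detection_p must be in (0, 1)")
        if not 0 < self.max_probe_missing_fraction < 1:
            raise ValidationError("max_probe_missing_fraction must be in (0, 1)")


@dataclass
class MValueMatrix:
    """Probes × samples matrix on the M-value (log2 ratio) scale."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("M-values must be finite")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class QCReport:
    """Per-probe fates plus tallies of masked measurements and dropped probes."""

    probe_fate: pd.DataFrame  # columns: probe_id, fate (kept/dropped), reason
    masked_measurements: dict[str, int] = field(default_factory=dict)
    n_input_probes: int = 0
    n_kept_probes: int = 0

    @property
    def dropped_by_reason(self) -> dict[str, int]:
        dropped = self.probe_fate[self.probe_fate["fate"] == "dropped"]
        return dropped["reason"].value_counts().to_dict()

    def summary(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_kept_probes": self.n_kept_probes,
            "n_dropped_probes": self.n_input_probes - self.n_kept_probes,
            "dropped_by_reason": self.dropped_by_reason,
            "masked_measurements": dict(self.masked_measurements),
        }

    def write(self, fate_path, summary_path=None) -> None:
        _write_tsv(self.probe_fate, fate_path)
        if summary_path is not None:
            with open(summary_path, "w") as handle:
                json.dump(self.summary(), handle, indent=2)


def mask_failed_measurements(
    beta: BetaMatrix, qc: ProbeQCMetrics, thresholds: QCThresholds = QCThresholds()
) -> tuple[BetaMatrix, dict[str, int]]:
    """Set failed probe×sample measurements to missing; all others untouched.

    Returns the masked matrix and a per-reason tally of newly masked cells
    (precedence bead > detection > zero-signal when a cell fails several).
    """
    if not qc.congruent_with(beta):
        raise ValidationError("QC metric dimensions do not match beta matrix")
    values = beta.data.to_numpy(dtype=float).copy()
    observed = ~np.isnan(values)
    bead_fail = qc.bead_count.to_numpy(dtype=float) < thresholds.min_bead_count
    det_fail = qc.detection_p.to_numpy(dtype=float) > thresholds.max_detection_p
    zero_fail = qc.signal_zero.to_numpy(dtype=bool)
    tally = {
        "bead": int((bead_fail & observed).sum()),
        "detection": int((det_fail & ~bead_fail & observed).sum()),
        "zero-signal": int((zero_fail & ~bead_fail & ~det_fail & observed).sum()),
    }
    values[bead_fail | det_fail | zero_fail] = np.nan
    masked = BetaMatrix(pd.DataFrame(values, index=beta.probe_ids, columns=beta.sample_ids))
    return masked, tally


def filter_probes(
    beta: BetaMatrix,
    cross_reactive: set[str] | None = None,
    thresholds: QCThresholds = QCThresholds(),
    masked_measurements: dict[str, int] | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Drop probes by the missingness rule, then cross-reactive removal.

    ``beta`` is expected to be measurement-masked already. Reasons are
    mutually exclusive: a high-missingness probe that is also on the
    cross-reactive list is recorded under ``missingness``.
    """
    cross_reactive = cross_reactive or set()
    missing_frac = beta.data.isna().mean(axis=1)
    high_missing = missing_frac > thresholds.max_probe_missing_fraction
    on_list = beta.probe_ids.isin(cross_reactive) & ~high_missing.to_numpy()

    reason = pd.Series(pd.NA, index=beta.probe_ids, dtype="object")
    reason[high_missing.to_numpy()] = "missingness"
    reason[on_list] = "cross-reactive"
    fate = pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "fate": np.where(reason.notna(), "dropped", "kept"),
            "reason": reason.to_numpy(),
        }
    )
    kept = BetaMatrix(beta.data.loc[reason.isna()])
    if kept.shape[0] == 0:
        logger.warning("all probes removed by QC filtering")
    report = QCReport(
        probe_fate=fate,
        masked_measurements=dict(masked_measurements or {}),
        n_input_probes=beta.shape[0],
        n_kept_probes=kept.shape[0],
    )
    return kept, report


def run_probe_qc(
    beta: BetaMatrix,
    qc: ProbeQCMetrics,
    cross_reactive: set[str] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[BetaMatrix, QCReport]:
    """Measurement masking followed by probe filtering, in one call."""
    masked, tally = mask_failed_measurements(beta, qc, thresholds)
    return filter_probes(masked, cross_reactive, thresholds, masked_measurements=tally)


def logit_transform(beta: BetaMatrix, epsilon: float = 1e-6) -> MValueMatrix:
    """Map beta values to M-values, log2(b/(1−b)), clipping b into [ε, 1−ε]."""
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    b = np.clip(beta.data.to_numpy(dtype=float), epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    m[np.isnan(beta.data.to_numpy(dtype=float))] = np.nan
    return MValueMatrix(pd.DataFrame(m, index=beta.probe_ids, columns=beta.sample_ids))


def inverse_logit_transform(mvalues: MValueMatrix) -> BetaMatrix:
    """Inverse of :func:`logit_transform`: b = 2^M / (1 + 2^M)."""
    m = mvalues.data.to_numpy(dtype=float)
    b = 1.0 / (1.0 + np.exp2(-m))
    return BetaMatrix(pd.DataFrame(b, index=mvalues.probe_ids, columns=mvalues.sample_ids))
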