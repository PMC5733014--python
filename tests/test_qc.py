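import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinewas.data_model import BetaMatrix, ProbeQCMetrics, ValidationError
from twinewas.qc import (
    QCThresholds,
    filter_probes,
    inverse_logit_transform,
    logit_transform,
    mask_failed_measurements,
    run_probe_qc,
)


def _metrics_like(beta, bead=10, det=0.001, zero=False):
    shape = beta.data.shape
    return ProbeQCMetrics(
        bead_count=pd.DataFrame(np.full(shape, bead), index=beta.probe_ids, columns=beta.sample_ids),
        detection_p=pd.DataFrame(np.full(shape, det), index=beta.probe_ids, columns=beta.sample_ids),
        signal_zero=pd.DataFrame(np.full(shape, zero), index=beta.probe_ids, columns=beta.sample_ids),
    )


def _beta(n_probes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return BetaMatrix(
        pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(n_probes, n_samples)),
            index=[f"cg{i:05d}" for i in range(n_probes)],
            columns=[f"S{i}" for i in range(n_samples)],
        )
    )


class TestMasking:
    def test_low_bead_count_masks_single_cell(self):
        beta = _beta(4, 3)
        qc = _metrics_like(beta)
        qc.bead_count.iloc[1, 2] = 2  # below the <3-bead cutoff
        masked, tally = mask_failed_measurements(beta, qc)
        assert np.isnan(masked.data.iloc[1, 2])
        assert masked.data.drop(index=masked.probe_ids[1]).notna().all().all()
        assert tally == {"bead": 1, "detection": 0, "zero-signal": 0}

    def test_detection_p_at_cutoff_retained(self):
        beta = _beta(2, 2)
        qc = _metrics_like(beta)
        qc.detection_p.iloc[0, 0] = 0.01  # strictly greater fails, equal passes
        qc.detection_p.iloc[1, 1] = 0.0101
        masked, tally = mask_failed_measurements(beta, qc)
        assert not np.isnan(masked.data.iloc[0, 0])
        assert np.isnan(masked.data.iloc[1, 1])
        assert tally["detection"] == 1

    def test_zero_signal_masks(self):
        beta = _beta(2, 2)
        qc = _metrics_like(beta)
        qc.signal_zero.iloc[0, 1] = True
        masked, tally = mask_failed_measurements(beta, qc)
        assert np.isnan(masked.data.iloc[0, 1])
        assert tally["zero-signal"] == 1

    def test_all_passing_leaves_values_untouched(self):
        beta = _beta(5, 4)
        masked, tally = mask_failed_measurements(beta, _metrics_like(beta))
        pd.testing.assert_frame_equal(masked.data, beta.data)
        assert sum(tally.values()) == 0

    def test_dimension_mismatch_rejected(self):
        beta = _beta(3, 3)
        qc = _metrics_like(_beta(2, 3))
        with pytest.raises(ValidationError, match="dimensions"):
            mask_failed_measurements(beta, qc)


class TestProbeFiltering:
    def test_missingness_rule_10pct_of_10_samples(self):
        beta = _beta(3, 10)
        beta.data.iloc[0, 0] = np.nan  # 1/10 = 10% > 5%
        kept, report = filter_probes(beta)
        assert list(kept.probe_ids) == list(beta.probe_ids[1:])
        fate = report.probe_fate.set_index("probe_id")
        assert fate.loc[beta.probe_ids[0], "reason"] == "missingness"

    def test_cross_reactive_fully_observed_probe_dropped(self):
        beta = _beta(3, 10)
        kept, report = filter_probes(beta, cross_reactive={"cg00001"})
        assert "cg00001" not in kept.probe_ids
        fate = report.probe_fate.set_index("probe_id")
        assert fate.loc["cg00001", "reason"] == "cross-reactive"

    def test_planted_failures_tally_exactly(self):
        # 100 probes: 3 high-missingness, 5 cross-reactive (disjoint) -> 92 kept
        beta = _beta(100, 20, seed=1)
        for p in (7, 21, 60):
            beta.data.iloc[p, :2] = np.nan  # 2/20 = 10% missing
        cross = {f"cg{i:05d}" for i in (3, 11, 40, 80, 99)}
        kept, report = filter_probes(beta, cross_reactive=cross)
        assert report.n_kept_probes == 92
        assert report.dropped_by_reason == {"missingness": 3, "cross-reactive": 5}
        assert report.n_input_probes == report.n_kept_probes + sum(
            report.dropped_by_reason.values()
        )

    def test_filtering_is_idempotent_and_preserves_values(self):
        beta = _beta(50, 12, seed=2)
        beta.data.iloc[4, :3] = np.nan
        kept, _ = filter_probes(beta, cross_reactive={"cg00010"})
        again, report = filter_probes(kept, cross_reactive={"cg00010"})
        pd.testing.assert_frame_equal(again.data, kept.data)
        assert report.n_kept_probes == report.n_input_probes
        pd.testing.assert_frame_equal(kept.data, beta.data.loc[kept.probe_ids])

    def test_full_qc_boundaries(self):
        """Bead = 2 fails, detection p = 0.01 passes, planted failures recovered."""
        beta = _beta(10, 40, seed=3)
        qc = _metrics_like(beta)
        qc.bead_count.iloc[0, 0] = 2
        qc.detection_p.iloc[1, 0] = 0.01
        qc.detection_p.iloc[2, :3] = 0.05  # 3/40 = 7.5% missing -> dropped
        qc.signal_zero.iloc[3, 0] = True
        kept, report = run_probe_qc(beta, qc, cross_reactive={"cg00005"})
        dropped = report.probe_fate.set_index("probe_id")
        assert dropped.loc["cg00002", "reason"] == "missingness"
        assert dropped.loc["cg00005", "reason"] == "cross-reactive"
        assert report.n_kept_probes == 8
        assert np.isnan(kept.data.loc["cg00000", "S0"])  # bead failure masked
        assert not np.isnan(kept.data.loc["cg00001", "S0"])  # p = 0.01 retained
        assert np.isnan(kept.data.loc["cg00003", "S0"])  # zero signal masked
        assert report.masked_measurements == {"bead": 1, "detection": 3, "zero-signal": 1}


class TestLogitTransform:
    @pytest.mark.parametrize(
        "b,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_known_values(self, b, expected):
        beta = BetaMatrix(pd.DataFrame([[b]], index=["cg1"], columns=["S1"]))
        m = logit_transform(beta)
        assert m.data.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_clips_to_epsilon(self):
        beta = BetaMatrix(pd.DataFrame([[0.0]], index=["cg1"], columns=["S1"]))
        m = logit_transform(beta, epsilon=1e-6)
        expected = np.log2(1e-6 / (1 - 1e-6))  # ~ -19.93
        assert m.data.iloc[0, 0] == pytest.approx(expected, abs=1e-9)
        assert m.data.iloc[0, 0] == pytest.approx(-19.93, abs=0.01)

    def test_missing_propagates(self):
        beta = BetaMatrix(pd.DataFrame([[np.nan, 0.4]], index=["cg1"], columns=["S1", "S2"]))
        m = logit_transform(beta)
        assert np.isnan(m.data.iloc[0, 0]) and not np.isnan(m.data.iloc[0, 1])

    @pytest.mark.parametrize("epsilon", [0.0, 0.5, -1e-3, 1.0])
    def test_bad_epsilon_rejected(self, epsilon):
        beta = _beta(2, 2)
        with pytest.raises(ValidationError):
            logit_transform(beta, epsilon=epsilon)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(min_value=1, max_value=9999), min_size=2, max_size=20, unique=True)
        .map(lambda ks: [k / 10000 for k in ks])
    )
    def test_strictly_increasing_and_odd(self, values):
        beta = BetaMatrix(
            pd.DataFrame([values], index=["cg1"], columns=[f"S{i}" for i in range(len(values))])
        )
        m = logit_transform(beta).data.to_numpy()[0]
        order = np.argsort(values)
        assert np.all(np.diff(m[order]) > 0)
        mirrored = BetaMatrix(
            pd.DataFrame([[1 - v for v in values]], index=["cg1"], columns=beta.sample_ids)
        )
        m2 = logit_transform(mirrored).data.to_numpy()[0]
        np.testing.assert_allclose(m2, -m, atol=1e-9)

    def test_inverse_recovers_clipped_betas(self):
        beta = _beta(20, 10, seed=4)
        m = logit_transform(beta, epsilon=1e-6)
        back = inverse_logit_transform(m)
        np.testing.assert_allclose(back.data.to_numpy(), beta.data.to_numpy(), atol=1e-12)


class TestThresholds:
    @pytest.mark.parametrize(
        "kwargs", [{"min_bead_count": 0}, {"max_detection_p": 0}, {"max_probe_missing_fraction": 1.0}]
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            QCThresholds(**kwargs)
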