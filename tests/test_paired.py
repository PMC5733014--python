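import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from twinewas.data_model import CELL_TYPES, CellCounts, ValidationError
from twinewas.paired import (
    COVARIATE_TERMS,
    build_pair_differences,
    run_paired_ewas,
    select_most_discordant,
)
from twinewas.qc import MValueMatrix

from conftest import make_cell_counts, make_sample_sheet


def _mvalues(n_probes, sample_ids, seed=0):
    rng = np.random.default_rng(seed)
    return MValueMatrix(
        pd.DataFrame(
            rng.normal(0, 1, size=(n_probes, len(sample_ids))),
            index=[f"cg{i:05d}" for i in range(n_probes)],
            columns=list(sample_ids),
        )
    )


def _phenotype(sample_ids, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0, 2, len(sample_ids)), index=list(sample_ids))


class TestBuildPairDifferences:
    def test_identical_twins_give_zero_deltas(self):
        sheet = make_sample_sheet(6)
        m = _mvalues(5, sheet.sample_ids, seed=1)
        # force both members of each pair to identical values
        for pid, (a, b) in sheet.complete_pairs().items():
            m.data[b] = m.data[a]
        phen = pd.Series(1.0, index=list(sheet.sample_ids))
        counts = make_cell_counts(sheet.sample_ids)
        for pid, (a, b) in sheet.complete_pairs().items():
            counts.data.loc[counts.data.sample_id == b, CELL_TYPES] = counts.data.loc[
                counts.data.sample_id == a, CELL_TYPES
            ].to_numpy()
        design = build_pair_differences(m, sheet, phen, counts)
        assert np.allclose(design.delta_m.to_numpy(), 0)
        assert np.allclose(design.covariates["delta_phenotype"], 0)
        assert np.allclose(design.covariates[[f"delta_{c}" for c in CELL_TYPES]], 0)

    def test_row_order_permutation_gives_identical_design(self):
        sheet = make_sample_sheet(8)
        m = _mvalues(10, sheet.sample_ids, seed=2)
        phen = _phenotype(sheet.sample_ids, seed=3)
        counts = make_cell_counts(sheet.sample_ids, seed=4)
        design = build_pair_differences(m, sheet, phen, counts)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(sheet.data))
        sheet2 = type(sheet)(sheet.data.iloc[perm].reset_index(drop=True))
        design2 = build_pair_differences(m, sheet2, phen, counts)
        pd.testing.assert_frame_equal(design.delta_m, design2.delta_m)
        pd.testing.assert_frame_equal(design.covariates, design2.covariates)

    def test_minuend_is_lexicographically_smaller(self):
        sheet = make_sample_sheet(4)
        design = build_pair_differences(
            _mvalues(3, sheet.sample_ids),
            sheet,
            _phenotype(sheet.sample_ids),
            make_cell_counts(sheet.sample_ids),
        )
        assert (design.orientation["minuend"] < design.orientation["subtrahend"]).all()

    def test_incomplete_and_unphenotyped_pairs_excluded_with_reason(self):
        sheet = make_sample_sheet(5, incomplete=1)
        phen = _phenotype(sheet.sample_ids)
        phen.loc["P0002A"] = np.nan
        design = build_pair_differences(
            _mvalues(3, sheet.sample_ids), sheet, phen, make_cell_counts(sheet.sample_ids)
        )
        assert design.n_pairs == 3
        reasons = design.excluded.set_index("pair_id")["reason"]
        assert reasons.loc["P0000"] == "incomplete pair"
        assert reasons.loc["P0002"] == "member missing phenotype"

    def test_full_cohort_yields_one_row_per_complete_pair(self):
        sheet = make_sample_sheet(243)
        design = build_pair_differences(
            _mvalues(2, sheet.sample_ids),
            sheet,
            _phenotype(sheet.sample_ids),
            make_cell_counts(sheet.sample_ids),
        )
        assert design.n_pairs == 243

    def test_pair_constant_shift_leaves_design_unchanged(self):
        """Adding any pair-constant to both twins' M-values cancels in deltas."""
        sheet = make_sample_sheet(10)
        m = _mvalues(8, sheet.sample_ids, seed=6)
        phen = _phenotype(sheet.sample_ids, seed=7)
        counts = make_cell_counts(sheet.sample_ids, seed=8)
        design = build_pair_differences(m, sheet, phen, counts)
        shifted = m.data.copy()
        rng = np.random.default_rng(9)
        for pid, (a, b) in sheet.complete_pairs().items():
            shift = rng.normal(0, 5, size=len(m.probe_ids))
            shifted[a] += shift
            shifted[b] += shift
        design2 = build_pair_differences(MValueMatrix(shifted), sheet, phen, counts)
        pd.testing.assert_frame_equal(design.delta_m, design2.delta_m, atol=1e-12, rtol=0)
        r1 = run_paired_ewas(design)
        r2 = run_paired_ewas(design2)
        pd.testing.assert_frame_equal(r1, r2, atol=1e-12, rtol=0)


class TestRunPairedEwas:
    def _design(self, n_pairs=12, n_probes=6, seed=0):
        sheet = make_sample_sheet(n_pairs)
        return build_pair_differences(
            _mvalues(n_probes, sheet.sample_ids, seed=seed),
            sheet,
            _phenotype(sheet.sample_ids, seed=seed + 1),
            make_cell_counts(sheet.sample_ids, seed=seed + 2),
        )

    def test_perfect_linear_relation_recovered(self):
        design = self._design(n_pairs=15)
        design.covariates[[f"delta_{c}" for c in CELL_TYPES]] = 0.0
        for probe in design.delta_m.columns:
            design.delta_m[probe] = 0.5 * design.covariates["delta_phenotype"]
        results = run_paired_ewas(design)
        np.testing.assert_allclose(results["estimate"], 0.5, atol=1e-10)

    def test_matches_statsmodels_ols_per_probe(self):
        """Independent matrix oracle on a 12-pair fixture."""
        design = self._design(n_pairs=12, n_probes=8, seed=3)
        results = run_paired_ewas(design).set_index("probe_id")
        X = np.column_stack(
            [np.ones(design.n_pairs), design.covariates[COVARIATE_TERMS[1:]].to_numpy()]
        )
        for probe in design.delta_m.columns:
            fit = sm.OLS(design.delta_m[probe].to_numpy(), X).fit()
            assert results.loc[probe, "estimate"] == pytest.approx(fit.params[1], abs=1e-10)
            assert results.loc[probe, "standard_error"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert results.loc[probe, "p_value"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_missing_measurements_use_complete_pairs(self):
        design = self._design(n_pairs=20, n_probes=3, seed=4)
        probe = design.delta_m.columns[0]
        design.delta_m.iloc[:3, 0] = np.nan
        results = run_paired_ewas(design).set_index("probe_id")
        assert results.loc[probe, "n_units"] == 17
        X = np.column_stack(
            [np.ones(design.n_pairs), design.covariates[COVARIATE_TERMS[1:]].to_numpy()]
        )[3:]
        fit = sm.OLS(design.delta_m[probe].to_numpy()[3:], X).fit()
        assert results.loc[probe, "estimate"] == pytest.approx(fit.params[1], abs=1e-10)

    def test_constant_phenotype_marks_results_unavailable(self):
        design = self._design(n_pairs=12)
        design.covariates["delta_phenotype"] = 0.0
        results = run_paired_ewas(design)
        assert results["estimate"].isna().all()

    def test_too_few_pairs_rejected(self):
        design = self._design(n_pairs=12)
        small = select_most_discordant(design, 0.5)  # 6 pairs < 10
        with pytest.raises(ValidationError, match="pairs"):
            run_paired_ewas(small)

    def test_null_pvalues_roughly_uniform(self):
        """No planted effect: the p-value distribution is uniform (KS)."""
        from scipy import stats

        sheet = make_sample_sheet(50)
        design = build_pair_differences(
            _mvalues(2000, sheet.sample_ids, seed=10),
            sheet,
            _phenotype(sheet.sample_ids, seed=11),
            make_cell_counts(sheet.sample_ids, seed=12),
        )
        results = run_paired_ewas(design)
        ks = stats.kstest(results["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestSelectMostDiscordant:
    def _design_with_deltas(self, deltas):
        sheet = make_sample_sheet(len(deltas))
        design = build_pair_differences(
            _mvalues(2, sheet.sample_ids),
            sheet,
            _phenotype(sheet.sample_ids),
            make_cell_counts(sheet.sample_ids),
        )
        design.covariates["delta_phenotype"] = deltas
        return design

    def test_keeps_largest_absolute_discordance(self):
        design = self._design_with_deltas([3.0, -2.0, 1.0, 0.0])
        kept = select_most_discordant(design, 0.5)
        assert sorted(kept.covariates["delta_phenotype"].abs()) == [2.0, 3.0]

    def test_ceiling_rule_on_odd_counts(self):
        design = self._design_with_deltas([5.0, 4.0, 3.0, 2.0, 1.0])
        assert select_most_discordant(design, 0.5).n_pairs == 3

    def test_fraction_one_is_identity(self):
        design = self._design_with_deltas([1.0, 2.0, 3.0])
        kept = select_most_discordant(design, 1.0)
        assert set(kept.pair_ids) == set(design.pair_ids)

    def test_ties_broken_by_pair_id(self):
        design = self._design_with_deltas([1.0, -1.0, 1.0, 0.5])
        kept = select_most_discordant(design, 0.5)
        assert list(kept.pair_ids) == ["P0000", "P0001"]

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        design = self._design_with_deltas([1.0, 2.0])
        with pytest.raises(ValidationError):
            select_most_discordant(design, fraction)
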