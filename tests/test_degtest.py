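import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from permdeg.expression_io import DesignError, ExpressionMatrix, PAIRED_ROLES
from permdeg.degtest import (
    DEGThresholds,
    RatioTable,
    StatisticUndefinedError,
    annotate_calls,
    attach_pvalues,
    build_null,
    call_degs,
    compute_ratios,
    count_distinct_permutations,
    empirical_pvalue,
    filter_low_expression,
    paired_statistics,
    per_subject_concordance_report,
    run_paired_deg,
    unpaired_statistics,
)
from conftest import make_paired_matrix, make_unpaired_matrix


def ratio_table_from_contrast(d):
    """RatioTable with OE_ratio = 2^d and KD_ratio = 1, so the log2
    contrast equals d exactly."""
    d = np.asarray(d, dtype=float)[None, :] if np.ndim(d) == 1 else np.asarray(d, float)
    return RatioTable(
        gene_ids=[f"G{i}" for i in range(d.shape[0])],
        subjects=[f"S{j}" for j in range(d.shape[1])],
        oe_ratio=np.exp2(d),
        kd_ratio=np.ones_like(d),
    )


class TestRatios:
    def test_identical_condition_and_control_columns_give_unit_ratio(self, paired_data):
        matrix, design = paired_data
        df = matrix.data.copy()
        for subj in design.subjects:
            df[design.assignments[subj]["OE"]] = df[design.assignments[subj]["OE_control"]]
        ratios = compute_ratios(ExpressionMatrix(df), design)
        np.testing.assert_allclose(ratios.oe_ratio, 1.0)

    def test_pseudocount_forces_unit_ratio_at_zero_expression(self):
        matrix, design = make_paired_matrix(n_genes=3)
        zeroed = ExpressionMatrix(matrix.data * 0.0 + 0.0)
        ratios = compute_ratios(zeroed, design, pseudocount=1.0)
        np.testing.assert_allclose(ratios.oe_ratio, 1.0)
        np.testing.assert_allclose(ratios.kd_ratio, 1.0)

    def test_hand_arithmetic_with_pseudocount(self):
        matrix, design = make_paired_matrix(n_genes=1)
        df = matrix.data.copy()
        df.loc[:, design.assignments["S1"]["OE"]] = 9.0
        df.loc[:, design.assignments["S1"]["OE_control"]] = 4.0
        ratios = compute_ratios(ExpressionMatrix(df), design, pseudocount=1.0)
        assert ratios.oe_ratio[0, 0] == pytest.approx(2.0)

    def test_missing_design_sample_is_a_lookup_error(self, paired_data):
        matrix, design = paired_data
        trimmed = ExpressionMatrix(matrix.data.drop(columns=["S1_KD"]))
        with pytest.raises(DesignError, match="S1_KD"):
            compute_ratios(trimmed, design)


class TestPairedStatistics:
    def test_equal_ratios_give_zero_statistic(self):
        rt = RatioTable(
            gene_ids=["g"],
            subjects=["S1", "S2", "S3"],
            oe_ratio=np.full((1, 3), 1.7),
            kd_ratio=np.full((1, 3), 1.7),
        )
        stats = paired_statistics(rt)
        assert stats["T"].iloc[0] == 0.0
        assert stats["log2FC"].iloc[0] == 0.0

    def test_closed_form_paired_t(self):
        stats = paired_statistics(ratio_table_from_contrast([0.8, 1.0, 1.2]))
        assert stats["log2FC"].iloc[0] == pytest.approx(1.0)
        assert stats["T"].iloc[0] == pytest.approx(1.0 / (0.2 / math.sqrt(3)), rel=1e-9)
        assert stats["T"].iloc[0] == pytest.approx(8.660254, rel=1e-6)

    def test_antisymmetry(self):
        d = np.array([[0.3, -0.1, 0.7], [1.0, 2.0, 1.5]])
        forward = paired_statistics(ratio_table_from_contrast(d))
        backward = paired_statistics(ratio_table_from_contrast(-d))
        np.testing.assert_allclose(backward["T"], -forward["T"])
        np.testing.assert_allclose(backward["log2FC"], -forward["log2FC"])

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(30, 4))
        stats = paired_statistics(ratio_table_from_contrast(d))
        expected = sps.ttest_rel(d, np.zeros_like(d), axis=1).statistic
        np.testing.assert_allclose(stats["T"], expected, rtol=1e-10)

    def test_single_subject_is_undefined(self):
        rt = RatioTable(["g"], ["S1"], np.array([[2.0]]), np.array([[1.0]]))
        with pytest.raises(StatisticUndefinedError):
            paired_statistics(rt)

    def test_constant_nonzero_contrast_is_degenerate(self):
        stats = paired_statistics(ratio_table_from_contrast([1.0, 1.0, 1.0]))
        assert stats["degenerate"].iloc[0]
        assert np.isnan(stats["T"].iloc[0])


class TestUnpairedStatistics:
    def build(self, case_log2, control_log2, pseudocount=1.0):
        cols = {}
        for i, v in enumerate(case_log2):
            cols[f"case{i}"] = [2.0 ** v - pseudocount]
        for i, v in enumerate(control_log2):
            cols[f"ctrl{i}"] = [2.0 ** v - pseudocount]
        matrix = ExpressionMatrix(pd.DataFrame(cols, index=["g"]))
        from permdeg.expression_io import UnpairedDesign

        design = UnpairedDesign(
            tuple(f"case{i}" for i in range(len(case_log2))),
            tuple(f"ctrl{i}" for i in range(len(control_log2))),
        )
        return matrix, design

    def test_identical_groups_give_zero_t(self):
        matrix, design = self.build([5, 6], [5, 6])
        stats = unpaired_statistics(matrix, design)
        assert stats["T"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_two_sample_t(self):
        matrix, design = self.build([5, 6], [3, 4])
        stats = unpaired_statistics(matrix, design)
        assert stats["log2FC"].iloc[0] == pytest.approx(2.0, rel=1e-9)
        assert stats["T"].iloc[0] == pytest.approx(2.828427, rel=1e-6)

    def test_matches_scipy_ttest_ind(self):
        matrix, design = make_unpaired_matrix(n_genes=25, seed=9)
        stats = unpaired_statistics(matrix, design, pseudocount=1.0)
        case = np.log2(matrix.columns(list(design.case_samples)) + 1.0)
        control = np.log2(matrix.columns(list(design.control_samples)) + 1.0)
        expected = sps.ttest_ind(case, control, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(stats["T"], expected, rtol=1e-10)

    def test_scaling_all_values_leaves_t_unchanged(self):
        matrix, design = make_unpaired_matrix(n_genes=10, seed=2)
        base = unpaired_statistics(matrix, design, pseudocount=0.0)
        scaled = unpaired_statistics(
            ExpressionMatrix(matrix.data * 7.5), design, pseudocount=0.0
        )
        np.testing.assert_allclose(scaled["T"], base["T"], rtol=1e-9)
        np.testing.assert_allclose(scaled["log2FC"], base["log2FC"], rtol=1e-9, atol=1e-12)


class TestEmpiricalPvalue:
    def test_brute_force_count(self):
        assert empirical_pvalue(1.5, np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == pytest.approx(0.5)

    def test_zero_observation_has_p_one(self):
        assert empirical_pvalue(0.0, np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == 1.0

    def test_floor_of_estimator(self):
        null = np.linspace(-1, 1, 999)
        assert empirical_pvalue(5.0, null) == pytest.approx(1.0 / 1000)

    def test_monotone_non_increasing_in_magnitude(self):
        rng = np.random.default_rng(3)
        null = rng.normal(size=500)
        obs = np.sort(np.abs(rng.normal(size=50)))
        p = empirical_pvalue(obs, null)
        assert (np.diff(p) <= 0).all()

    def test_empty_null_rejected(self):
        with pytest.raises(StatisticUndefinedError):
            empirical_pvalue(1.0, np.array([]))


class TestBuildNull:
    def test_pool_size_bookkeeping(self):
        matrix, design = make_paired_matrix(n_genes=5)
        null_t, null_f = build_null(matrix, design, n_permutations=2, seed=0, mode="montecarlo")
        assert len(null_t) + null_t.n_dropped == 2 * 5
        assert len(null_f) == 2 * 5

    def test_same_seed_reproduces_null(self):
        matrix, design = make_paired_matrix(n_genes=8)
        a = build_null(matrix, design, 20, seed=13, mode="montecarlo")
        b = build_null(matrix, design, 20, seed=13, mode="montecarlo")
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_excess_b_on_tiny_design_warns(self):
        matrix, design = make_paired_matrix(n_genes=3, n_subjects=2)
        with pytest.warns(UserWarning, match="duplicate permutations"):
            build_null(matrix, design, 600, seed=0, mode="montecarlo")

    def test_auto_mode_enumerates_small_designs_exactly(self):
        matrix, design = make_paired_matrix(n_genes=4, n_subjects=2, seed=7)
        auto = build_null(matrix, design, 576, seed=0, mode="auto")
        forced = build_null(matrix, design, 1, seed=99, mode="exhaustive")
        np.testing.assert_array_equal(np.sort(auto[0].values), np.sort(forced[0].values))
        assert auto[0].n_permutations == count_distinct_permutations(design)

    def test_unpaired_exhaustive_matches_combination_oracle(self):
        matrix, design = make_unpaired_matrix(n_genes=6, n_case=2, n_control=2, seed=4)
        null_t, null_f = build_null(matrix, design, 6, seed=0, mode="auto")
        X = np.log2(matrix.columns(design.sample_ids()) + 1.0)
        expected_t = []
        for case_idx in itertools.combinations(range(4), 2):
            control_idx = [i for i in range(4) if i not in case_idx]
            t = sps.ttest_ind(
                X[:, list(case_idx)], X[:, control_idx], axis=1, equal_var=True
            ).statistic
            expected_t.append(t)
        np.testing.assert_allclose(
            np.sort(null_t.values), np.sort(np.concatenate(expected_t)), rtol=1e-10
        )

    def test_across_samples_scheme_runs_and_differs(self):
        matrix, design = make_paired_matrix(n_genes=10, seed=5)
        within = build_null(matrix, design, 50, seed=1, mode="montecarlo")
        across = build_null(
            matrix, design, 50, seed=1, scheme="across_samples", mode="montecarlo"
        )
        assert len(across[0]) + across[0].n_dropped == 50 * 10
        assert not np.array_equal(np.sort(within[0].values), np.sort(across[0].values))


class TestCallsAndReports:
    def make_stats(self, pt, pf, lfc):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(len(pt))],
                "T": np.sign(lfc) * 3.0,
                "log2FC": lfc,
                "degenerate": False,
                "Pt": pt,
                "Pf": pf,
            }
        )

    def test_all_null_pvalues_give_empty_set(self):
        stats = self.make_stats([1.0, 1.0], [1.0, 1.0], [1.0, -1.0])
        degs = call_degs(stats, DEGThresholds(), kind="paired")
        assert len(degs) == 0

    def test_thresholds_are_inclusive(self):
        stats = self.make_stats([0.05], [0.10], [2.0])
        degs = call_degs(stats, DEGThresholds(), kind="paired")
        assert degs.members == {"G0"}
        assert degs.directions()["G0"] == "induced"

    def test_direction_follows_log2fc_sign(self):
        stats = self.make_stats([0.01, 0.01], [0.01, 0.01], [1.5, -1.5])
        annotated = annotate_calls(stats, DEGThresholds(), kind="unpaired")
        assert annotated["direction"].tolist() == ["up", "down"]

    def test_concordance_report_flags_and_row_count(self):
        d = np.array([[1.1, 0.9, 1.3], [1.1, -0.2, 1.3]])
        ratios = ratio_table_from_contrast(d)
        stats = self.make_stats([0.01, 0.01], [0.01, 0.01], d.mean(axis=1))
        degs = call_degs(stats, DEGThresholds(), kind="paired")
        report = per_subject_concordance_report(ratios, degs)
        assert len(report) == len(degs) == 2
        assert report.set_index("gene_id").loc["G0", "concordant"]
        assert not report.set_index("gene_id").loc["G1", "concordant"]

    def test_degenerate_gene_gets_pf_as_pt_with_warning(self):
        stats = paired_statistics(
            ratio_table_from_contrast(np.array([[1.0, 1.0, 1.0], [0.5, 0.2, 0.9]]))
        )
        null = np.random.default_rng(0).normal(size=200)
        from permdeg.degtest import NullDistribution

        null_t = NullDistribution("T", null, 20, 10)
        null_f = NullDistribution("log2FC", null, 20, 10)
        with pytest.warns(UserWarning, match="zero contrast variance"):
            out = attach_pvalues(stats, null_t, null_f)
        assert out["Pt"].iloc[0] == out["Pf"].iloc[0]


class TestPipelineProperties:
    def test_pvalue_bounds_and_determinism(self):
        matrix, design = make_paired_matrix(n_genes=40, seed=21)
        thresholds = DEGThresholds(n_permutations=100)
        res1 = run_paired_deg(matrix, design, thresholds, seed=5)
        res2 = run_paired_deg(matrix, design, thresholds, seed=5)
        pd.testing.assert_frame_equal(res1.stats, res2.stats)
        n_t, n_f = len(res1.null_t), len(res1.null_f)
        assert res1.stats["Pt"].between(1 / (n_t + 1), 1).all()
        assert res1.stats["Pf"].between(1 / (n_f + 1), 1).all()

    def test_swapping_case_control_flips_directions_not_pvalues(self):
        matrix, design = make_unpaired_matrix(n_genes=10, n_case=2, n_control=2, seed=8)
        from permdeg.expression_io import UnpairedDesign
        from permdeg.degtest import run_unpaired_deg

        swapped = UnpairedDesign(design.control_samples, design.case_samples)
        a = run_unpaired_deg(matrix, design, DEGThresholds(n_permutations=6), seed=1)
        b = run_unpaired_deg(matrix, swapped, DEGThresholds(n_permutations=6), seed=1)
        np.testing.assert_allclose(b.stats["log2FC"], -a.stats["log2FC"], rtol=1e-10)
        np.testing.assert_allclose(b.stats["Pt"], a.stats["Pt"], rtol=1e-12)
        np.testing.assert_allclose(b.stats["Pf"], a.stats["Pf"], rtol=1e-12)

    def test_low_expression_filter_drops_and_counts(self):
        matrix, design = make_paired_matrix(n_genes=5)
        df = matrix.data.copy()
        df.iloc[0] = 0.01  # everywhere below the pseudocount
        filtered, n_dropped = filter_low_expression(
            ExpressionMatrix(df), design.sample_ids(), threshold=1.0
        )
        assert n_dropped == 1
        assert filtered.n_genes == 4
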