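"""Two-group inference, BH adjustment, cutoff grids, suite consistency, FPKM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hstlkit.diffexpr import (
    ComparisonSuite,
    CountMatrix,
    DiffExprError,
    ExpressionMatrix,
    apply_cutoffs,
    bh_fdr,
    consistency_select,
    fit_two_group,
    fpkm,
    merge_fc_table,
    read_expression_tsv,
    region_overlap,
    run_comparison_suite,
    signed_fc,
    write_expression_tsv,
)
from hstlkit.segments import Region


def _matrix(values, groups, labs=None, platform="microarray"):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(values[0]))],
    )
    return ExpressionMatrix(
        values=df,
        groups=pd.Series(groups, index=df.columns),
        labs=pd.Series(labs, index=df.columns) if labs else None,
        platform=platform,
    )


class TestSignedFC:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0), (3.9068906, 15.0)],
    )
    def test_known_values(self, delta, expected):
        assert signed_fc(delta) == pytest.approx(expected, abs=1e-4)

    def test_printed_downregulation_convention(self):
        # a 1.5907 log2 drop prints as a fold change of -3.012
        assert signed_fc(-1.5907) == pytest.approx(-3.012, abs=1e-3)

    def test_never_in_the_open_unit_interval(self):
        deltas = np.linspace(-4, 4, 101)
        fc = signed_fc(deltas)
        assert (np.abs(fc) >= 1.0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(DiffExprError):
            signed_fc(float("nan"))


def _bh_oracle(p):
    """Literal step-up: q_i = min_{k: p_k >= p_i-rank} (m * p_k / rank_k), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBHFDR:
    def test_single_p_value_unchanged(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_uniform_spacing_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_monotone_on_sorted_inputs(self):
        q = bh_fdr(np.linspace(0.001, 0.9, 30))
        assert (np.diff(q) >= -1e-12).all()

    def test_matches_step_up_oracle_exhaustively_small(self):
        grid = [0.0, 0.01, 0.049, 0.05, 0.2, 0.5, 1.0]
        for m in (1, 2, 3):
            for p in itertools.product(grid, repeat=m):
                assert bh_fdr(list(p)) == pytest.approx(_bh_oracle(np.array(p)))

    def test_matches_step_up_oracle_random_up_to_twelve(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = int(rng.integers(1, 13))
            p = rng.random(m)
            assert bh_fdr(p) == pytest.approx(_bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffExprError):
            bh_fdr([0.5, 1.5])


class TestFitTwoGroup:
    def test_toy_matrix_equals_pooled_t_test(self):
        values = [[1.0, 2.0, 5.0, 7.0], [3.0, 3.5, 2.0, 1.0]]
        m = _matrix(values, ["A", "A", "B", "B"])
        res = fit_two_group(m, "A", "B")
        for i, row in enumerate(values):
            t, p = stats.ttest_ind(row[:2], row[2:], equal_var=True)
            assert res["t_statistic"].iloc[i] == pytest.approx(t)
            assert res["p_value"].iloc[i] == pytest.approx(p)
            assert res["delta_log2"].iloc[i] == pytest.approx(
                np.mean(row[:2]) - np.mean(row[2:])
            )

    def test_identical_values_give_null_result(self):
        m = _matrix([[2.0, 2.0, 2.0, 2.0]], ["A", "A", "B", "B"])
        res = fit_two_group(m, "A", "B")
        assert res["delta_log2"].iloc[0] == 0.0
        assert res["signed_fc"].iloc[0] == 1.0
        assert res["p_value"].iloc[0] == 1.0

    def test_swapping_groups_negates_effect_keeps_p(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(5, 1, (10, 8)).tolist(), ["A"] * 4 + ["B"] * 4)
        ab = fit_two_group(m, "A", "B")
        ba = fit_two_group(m, "B", "A")
        assert ab["delta_log2"].to_numpy() == pytest.approx(
            -ba["delta_log2"].to_numpy()
        )
        assert ab["signed_fc"].to_numpy() == pytest.approx(-ba["signed_fc"].to_numpy())
        assert ab["p_value"].to_numpy() == pytest.approx(ba["p_value"].to_numpy())

    def test_planted_effect_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            null = rng.normal(5.0, 0.25, (200, 20))
            planted = null[0].copy()
            planted[:10] += 1.0  # true delta_log2 = 1.0
            values = np.vstack([planted, null[1:]])
            m = _matrix(values.tolist(), ["A"] * 10 + ["B"] * 10)
            res = fit_two_group(m, "A", "B")
            ok = (
                abs(res["delta_log2"].iloc[0] - 1.0) <= 0.25
                and res["q_value"].iloc[0] < 0.05
            )
            hits += ok
        assert hits >= 19  # >= 95% of seeds

    def test_small_group_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0]], ["A", "B", "B"])
        with pytest.raises(DiffExprError, match="fewer than 2"):
            fit_two_group(m, "A", "B")

    def test_lab_covariate_absorbs_batch_offset(self):
        rng = np.random.default_rng(11)
        n = 12
        labs = ["lab1", "lab2"] * (n // 2)
        offset = np.array([2.0 if lab == "lab2" else 0.0 for lab in labs])
        values = rng.normal(5, 0.3, (50, n)) + offset
        m = _matrix(values.tolist(), ["A"] * 6 + ["B"] * 6, labs=labs)
        naive = fit_two_group(m, "A", "B", adjust_lab=False)
        adjusted = fit_two_group(m, "A", "B", adjust_lab=True)
        # balanced design: the covariate shrinks residual noise
        assert adjusted["p_value"].median() <= naive["p_value"].median()
        assert np.isfinite(adjusted["t_statistic"]).all()


class TestCutoffs:
    @pytest.mark.parametrize(
        "fc,q,kept",
        [(15.0, 0.001, True), (1.9, 0.001, False), (-2.0, 0.05, True), (2.5, 0.06, False)],
    )
    def test_inclusive_thresholds(self, fc, q, kept):
        res = pd.DataFrame({"signed_fc": [fc], "q_value": [q]}, index=["g"])
        selected = apply_cutoffs(res, abs_fc_min=2.0, fdr_max=0.05)
        assert ("g" in selected.index) == kept


class TestComparisonSuite:
    def test_default_suite_has_ten_labeled_tables(self, small_cohort):
        _, expr = small_cohort
        suite = run_comparison_suite(
            {"microarray": expr["microarray"], "rnaseq": expr["rnaseq"]}
        )
        assert len(suite) == 10
        assert len(set(suite.comparison_ids)) == 10

    def test_single_comparison_degenerate_suite(self, small_cohort):
        _, expr = small_cohort
        suite = run_comparison_suite(
            {"microarray": expr["microarray"]}, suite=[("microarray", "PTCL")]
        )
        assert suite.comparison_ids == ["MA:vs_PTCL"]

    def test_missing_reference_group_named_in_error(self, small_cohort):
        _, expr = small_cohort
        with pytest.raises(DiffExprError, match="THYMUS"):
            run_comparison_suite(
                {"microarray": expr["microarray"]}, suite=[("microarray", "THYMUS")]
            )

    def test_planted_up_gene_positive_in_all_comparisons(self, small_cohort):
        _, expr = small_cohort
        suite = run_comparison_suite(
            {"microarray": expr["microarray"], "rnaseq": expr["rnaseq"]}
        )
        gene = expr["truth"]["roles"]["signature_up"][0]
        for table in suite.tables.values():
            assert table.loc[gene, "signed_fc"] > 0


class TestConsistency:
    def test_tallies_match_naive_counting(self):
        rng = np.random.default_rng(13)
        grid = pd.DataFrame(
            rng.choice([np.nan, 3.0, -3.0], size=(50, 10), p=[0.6, 0.2, 0.2]),
            index=[f"g{i}" for i in range(50)],
        )
        from hstlkit.diffexpr import ConsistencyTable

        table = ConsistencyTable(grid=grid)
        for gene in grid.index:
            row = grid.loc[gene]
            assert table.n_up[gene] == sum(1 for v in row if v > 0)
            assert table.n_down[gene] == sum(1 for v in row if v < 0)
        assert (table.n_up + table.n_down).equals(table.n_significant)

    def test_consistent_up_and_mixed_sign_rules(self):
        from hstlkit.diffexpr import ConsistencyTable

        rows = {
            "up7": [4.0] * 7 + [np.nan] * 3,
            "mixed": [3.0, 3.0, 3.0, -2.5] + [np.nan] * 6,
            "up10": [2.0] * 10,
        }
        grid = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"c{k}" for k in range(10)])
        table = ConsistencyTable(grid=grid)
        assert "up7" in consistency_select(table, 4)
        assert "mixed" not in consistency_select(table, 1)
        assert "up10" in consistency_select(table, 10)

    def test_monotone_in_min_comparisons(self, small_cohort):
        _, expr = small_cohort
        suite = run_comparison_suite(
            {"microarray": expr["microarray"], "rnaseq": expr["rnaseq"]}
        )
        table = merge_fc_table(suite)
        previous = None
        for k in range(1, 11):
            selected = set(consistency_select(table, k))
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_planted_signature_selected_at_full_consistency(self, small_cohort):
        _, expr = small_cohort
        suite = run_comparison_suite(
            {"microarray": expr["microarray"], "rnaseq": expr["rnaseq"]}
        )
        table = merge_fc_table(suite, abs_fc_min=2.0, fdr_max=0.05)
        selected = set(consistency_select(table, 10))
        assert set(expr["truth"]["planted_consistent"]) <= selected


class TestFPKM:
    def _counts(self, counts, lengths, mapped):
        df = pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(len(counts))],
            columns=[f"s{j}" for j in range(len(counts[0]))],
        )
        return CountMatrix(
            counts=df,
            gene_length_bp=pd.Series(lengths, index=df.index),
            mapped_reads=pd.Series(mapped, index=df.columns),
        )

    def test_direct_formula(self):
        cm = self._counts([[1000]], [2000], [50_000_000])
        assert fpkm(cm).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        cm = self._counts([[0]], [2000], [50_000_000])
        assert fpkm(cm).iloc[0, 0] == 0.0

    def test_doubling_depth_halves_fpkm(self):
        cm1 = self._counts([[500], [80]], [1000, 4000], [10_000_000])
        cm2 = self._counts([[500], [80]], [1000, 4000], [20_000_000])
        assert fpkm(cm2).to_numpy() == pytest.approx(fpkm(cm1).to_numpy() / 2)

    def test_invalid_length_rejected(self):
        with pytest.raises(DiffExprError):
            self._counts([[1]], [0], [1_000_000])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DiffExprError):
            self._counts([[1.5]], [100], [1_000_000])


class TestRegionOverlap:
    CGR = Region("7", 86259620, 124892276, "CGR", ("case1", "case3"), 2)

    def test_printed_gene_positions(self):
        genes = pd.DataFrame(
            {"chromosome": ["7", "7"], "position": [87133175, 29234120]},
            index=["ABCB1", "CHN2"],
        )
        inside = region_overlap(genes, self.CGR)
        assert list(inside.index) == ["ABCB1"]

    def test_boundaries_are_inclusive(self):
        genes = pd.DataFrame(
            {"chromosome": ["7", "7", "7"],
             "position": [86259620, 124892276, 124892277]},
            index=["at_start", "at_end", "past_end"],
        )
        inside = region_overlap(genes, self.CGR)
        assert list(inside.index) == ["at_start", "at_end"]

    def test_empty_region_selects_nothing(self):
        genes = pd.DataFrame({"chromosome": ["7"], "position": [1]}, index=["g"])
        assert region_overlap(genes, Region.empty("7", "CDR")).empty


def test_expression_tsv_round_trip(tmp_path, small_cohort):
    _, expr = small_cohort
    path = tmp_path / "ma.tsv"
    write_expression_tsv(expr["microarray"], path)
    back = read_expression_tsv(path)
    pd.testing.assert_frame_equal(
        back.values, expr["microarray"].values,
        check_exact=False, atol=1e-9, check_names=False,
    )
    assert back.groups.to_list() == expr["microarray"].groups.to_list()
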