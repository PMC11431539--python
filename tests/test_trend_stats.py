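"""Statistical operations against independent definitional oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import postopsat as pos

from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles (definitional formulas, no shared code path)


def anova_oracle(groups):
    """F from the raw sum-of-squares decomposition."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def midranks(values):
    """Average ranks for ties, built from sorting alone."""
    v = np.asarray(values, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation applied to midranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1) for k in support}
    cutoff = pmf[a] * (1 + 1e-7)  # relative tolerance for float ties
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


# ---------------------------------------------------------------------------


class TestLikertSummary:
    def test_cell_mean_and_count(self):
        records = [make_record(q2_postop_care=v) for v in (5, 5, 4)]
        ds = pos.SurveyDataset.from_records(records)
        (cell,) = pos.likert_summary(ds, "q2_postop_care", grouping="ward_year")
        assert cell.n == 3
        assert cell.mean == pytest.approx(14 / 3)
        assert 1 <= cell.mean <= 5

    def test_single_response_cell_has_zero_sd(self):
        ds = pos.SurveyDataset.from_records([make_record(q2_postop_care=3)])
        (cell,) = pos.likert_summary(ds, "q2_postop_care", grouping="year")
        assert cell.mean == 3 and cell.sd == 0.0

    def test_missing_answers_dropped_per_cell(self):
        records = [make_record(q2_postop_care=5), make_record(q2_postop_care=None)]
        (cell,) = pos.likert_summary(pos.SurveyDataset.from_records(records), "q2_postop_care")
        assert cell.n == 1

    def test_unknown_question_rejected(self):
        with pytest.raises(ValueError):
            pos.likert_summary(pos.SurveyDataset.from_records([make_record()]), "q9")


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p, df_b, df_w = pos.anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)
        assert (df_b, df_w) == (1, 4)

    def test_zero_within_variance_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.anova_oneway([[1, 1, 1], [2, 2, 2]])

    @pytest.mark.parametrize("seed", range(5))
    def test_f_matches_sum_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 12)) for _ in range(4)]
        f, p, _, _ = pos.anova_oneway(groups)
        assert f == pytest.approx(anova_oracle(groups), rel=1e-10)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 15)
        f, p_f, _, _ = pos.anova_oneway([a, b])
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)


class TestTukey:
    def test_identical_groups_never_rejected(self):
        table = pos.tukey_hsd([[1, 2, 3]] * 3 + [[1, 2, 3.0001]])
        assert (table["p_adj"] > 0.999).all()
        assert not table["reject"].any()

    def test_two_groups_match_studentized_range_closed_form(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        table = pos.tukey_hsd([a, b])
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        p_expected = sps.studentized_range.sf(abs(t) * math.sqrt(2), 2, len(a) + len(b) - 2)
        assert table.loc[0, "p_adj"] == pytest.approx(p_expected, rel=1e-6)

    def test_shifted_group_is_the_only_one_flagged(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.5, 15)
        b = rng.normal(0, 0.5, 15)
        c = rng.normal(8, 0.5, 15)
        table = pos.tukey_hsd([a, b, c]).set_index(["group_i", "group_j"])
        assert not table.loc[(0, 1), "reject"]
        assert table.loc[(0, 2), "reject"] and table.loc[(1, 2), "reject"]


class TestContingency:
    def test_identical_rows_give_zero_chi_square(self):
        meth, stat, p = pos.contingency_test([[10, 10], [10, 10]], method="chi_square")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_diagonal_table_fisher_p(self):
        # 2/252: only the two perfectly separated tables are as extreme
        meth, _, p = pos.contingency_test([[5, 0], [0, 5]], method="fisher")
        assert meth == "fisher"
        assert p == pytest.approx(2 / 252, rel=1e-10)
        assert p == pytest.approx(fisher_oracle([[5, 0], [0, 5]]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_fisher_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 16, size=(2, 2))
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            table = table + 1
        _, _, p = pos.contingency_test(table.tolist(), method="fisher")
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_auto_selects_fisher_for_sparse_2x2(self):
        meth, _, _ = pos.contingency_test([[2, 1], [1, 3]], method="auto")
        assert meth == "fisher"
        meth, _, _ = pos.contingency_test([[20, 15], [18, 22]], method="auto")
        assert meth == "chi_square"

    def test_zero_margin_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.contingency_test([[0, 0], [3, 4]])


class TestPairedT:
    def test_hand_computed_small_sample(self):
        res = pos.paired_t([1, 2, 3])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.t_stat == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-4)
        assert res.df == 2

    def test_all_zero_differences_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.paired_t([0.0, 0.0, 0.0])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pos.paired_t([1.0])

    @pytest.mark.parametrize(
        "mean, sd, expected_t, expected_p",
        [
            (0.58667, 0.38857, 3.698, 0.014),
            (0.65167, 0.51316, 3.111, 0.027),
            (-0.06500, 0.61452, -0.259, 0.806),
        ],
    )
    def test_published_summary_rows_reproduced(self, mean, sd, expected_t, expected_p):
        res = pos.paired_t_from_summary(mean, sd, 6)
        assert round(res.t_stat, 3) == expected_t
        assert round(res.p_two_sided, 3) == expected_p

    def test_published_ci_bounds_reproduced_to_rounding(self):
        res = pos.paired_t_from_summary(0.58667, 0.38857, 6)
        assert res.ci95_low == pytest.approx(0.17889, abs=2e-4)
        assert res.ci95_high == pytest.approx(0.99445, abs=2e-4)

    @given(
        diffs=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=2, max_size=30
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_raw_and_summary_paths_agree(self, diffs):
        d = np.asarray(diffs)
        if d.std(ddof=1) == 0:
            return
        raw = pos.paired_t(d)
        summ = pos.paired_t_from_summary(float(d.mean()), float(d.std(ddof=1)), len(d))
        assert raw.t_stat == pytest.approx(summ.t_stat, abs=1e-10)
        assert raw.p_two_sided == pytest.approx(summ.p_two_sided, abs=1e-10)
        assert raw.ci95_low == pytest.approx(summ.ci95_low, abs=1e-10)
        assert raw.ci95_low <= raw.mean_diff <= raw.ci95_high
        if raw.sd_diff > 0:
            assert np.sign(raw.t_stat) == np.sign(raw.mean_diff) or raw.mean_diff == 0

    def test_two_sided_p_matches_scipy_one_sample(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1, 20)
        res = pos.paired_t(d)
        t, p = sps.ttest_1samp(d, 0.0)
        assert res.t_stat == pytest.approx(t, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)


class TestShapiroGate:
    def test_discrete_likert_sample_rejects_normality(self):
        rng = np.random.default_rng(0)
        sample = rng.integers(1, 6, size=500)
        w, p = pos.shapiro_wilk(sample)
        assert 0 < w <= 1
        assert p < 0.05

    def test_type_i_error_near_nominal_for_normal_data(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(200):
            _, p = pos.shapiro_wilk(rng.normal(size=50))
            rejections += p < 0.05
        assert abs(rejections / 200 - 0.05) <= 0.04

    def test_constant_sample_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.shapiro_wilk([2.0] * 10)


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert pos.spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert pos.spearman_rho(x, x[::-1])[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_tied_instances_match_midrank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        x = rng.integers(1, 6, size=n)
        y = rng.integers(1, 6, size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, _ = pos.spearman_rho(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    @given(
        xs=st.lists(st.integers(min_value=1, max_value=5), min_size=4, max_size=40),
        shift=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_invariant_under_strictly_monotone_transform(self, xs, shift):
        rng = np.random.default_rng(0)
        ys = rng.integers(1, 6, size=len(xs))
        x = np.asarray(xs)
        if np.ptp(x) == 0 or np.ptp(ys) == 0:
            return
        rho1, _ = pos.spearman_rho(x, ys)
        rho2, _ = pos.spearman_rho(np.exp(x) + shift, ys**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.spearman_rho([1, 1, 1], [1, 2, 3])


class TestCronbach:
    def test_duplicated_columns_give_alpha_one(self):
        assert pos.cronbach_alpha([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)
        mat = np.tile(np.arange(10.0)[:, None], (1, 4))
        assert pos.cronbach_alpha(mat) == pytest.approx(1.0)

    def test_independent_columns_give_alpha_near_zero(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(2000, 2))
        assert abs(pos.cronbach_alpha(mat)) <= 0.1

    def test_matches_pingouin_on_random_matrix(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 1))
        mat = base + rng.normal(scale=0.8, size=(200, 3))
        alpha, _ = pingouin.cronbach_alpha(data=pd.DataFrame(mat))
        assert pos.cronbach_alpha(mat) == pytest.approx(alpha, abs=1e-10)

    def test_rowwise_deletion_of_missing(self):
        mat = pd.DataFrame({"a": [1, 2, 3, np.nan], "b": [1, 2, 3, 9]})
        assert pos.cronbach_alpha(mat) == pytest.approx(1.0)

    def test_zero_total_variance_signalled(self):
        with pytest.raises(pos.DegenerateStatisticError):
            pos.cronbach_alpha([[1, 2], [2, 1], [1, 2]])


class TestYearlyScoreSummary:
    def test_small_sample_summary(self):
        scores = pd.DataFrame({"year": [2020] * 3, "total_score": [1.0, 2.0, 3.0]})
        (s,) = pos.yearly_score_summary(scores)
        assert (s.mean, s.median, s.sd) == (2.0, 2.0, 1.0)
        assert s.iqr_low <= s.median <= s.iqr_high

    def test_single_score_year_reports_missing_sd(self):
        scores = pd.DataFrame({"year": [2021], "total_score": [1.7]})
        (s,) = pos.yearly_score_summary(scores)
        assert s.mean == s.median == 1.7
        assert s.sd is None


class TestPipeline:
    def test_default_cohort_produces_all_ten_year_pairs(self, retained_cohort):
        report = pos.run_pipeline(retained_cohort)
        assert len(report.paired_tests) == math.comb(5, 2) == 10
        labels = set(report.paired_tests["label"])
        years = range(2019, 2024)
        assert labels == {f"{a}-{b}" for a, b in itertools.combinations(years, 2)}
        assert report.correlation["method"] == "spearman"
        assert not report.normality["normal"].any()

    def test_two_year_cohort_produces_one_pair(self, default_config):
        import copy

        cfg = copy.deepcopy(default_config)
        cfg.cell_counts = {
            w: {y: (n if y in (2019, 2020) else 0) for y, n in by.items()}
            for w, by in cfg.cell_counts.items()
        }
        cohort = pos.generate_cohort(cfg)
        retained, _, _ = pos.apply_exclusion(cohort)
        report = pos.run_pipeline(retained)
        assert len(report.paired_tests) == 1

    def test_cohort_without_operated_patients_skips_scoring_not_q3(self):
        records = [
            make_record(year=y, ward=w, q1_surgery="no", q2_postop_care=None,
                        infection=None, complication=None, protocol=None,
                        innovation=None, pain=None, q3_overall=1 + (i % 5))
            for i, (y, w) in enumerate(
                itertools.product(range(2019, 2022), ["ent", "urology"])
            )
            for _ in range(10)
        ]
        report = pos.run_pipeline(pos.SurveyDataset.from_records(records))
        assert any(s["analysis"] == "scoring" for s in report.skipped)
        assert report.scores is None
        q3_rows = report.likert_means.query("question == 'q3_overall'")
        assert len(q3_rows) > 0

    def test_report_saves_expected_tables(self, retained_cohort, tmp_path):
        report = pos.run_pipeline(retained_cohort)
        report.save(tmp_path)
        for name in (
            "counts.csv", "ward_year_counts.csv", "ages.csv", "surgery_rates.csv",
            "likert_means.csv", "scores_by_year.csv", "paired_tests.csv",
            "correlation.csv", "summary.json",
        ):
            assert (tmp_path / name).exists()

    def test_holm_adjustment_is_monotone_and_bounded(self, retained_cohort):
        cfg = pos.AnalysisConfig(multiple_correction="holm")
        report = pos.run_pipeline(retained_cohort, config=cfg)
        adj = report.paired_tests["p_adjusted"]
        raw = report.paired_tests["p_two_sided"]
        assert (adj >= raw - 1e-15).all() and (adj <= 1.0).all()
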