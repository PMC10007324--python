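import numpy as np
import pytest
from scipy import stats

import stressprofile as sp
from stressprofile.cohort import _exact_signed_rank_cdf


class TestDescriptives:
    def test_reference_cohort_moments(self, reference_cohort):
        mean, sd, var = sp.descriptives(reference_cohort.pre)
        assert round(mean, 3) == 0.247
        assert var == pytest.approx(0.0092543, abs=2e-6)  # 3-dp fixture quantization
        mean2, _, var2 = sp.descriptives(reference_cohort.post)
        assert round(mean2, 3) == 0.321
        assert var2 == pytest.approx(0.03026685, abs=2e-5)

    def test_trivial_and_error_cases(self):
        mean, sd, var = sp.descriptives([1.0, 1.0, 1.0])
        assert (mean, sd, var) == (1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            sp.descriptives([1.0])


class TestWelch:
    def test_matches_textbook_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(0, 1, size=rng.integers(2, 40))
            y = rng.normal(0.3, 2, size=rng.integers(2, 40))
            res = sp.welch_t(x, y)
            v1, v2 = x.var(ddof=1), y.var(ddof=1)
            se2 = v1 / x.size + v2 / y.size
            t = (x.mean() - y.mean()) / np.sqrt(se2)
            df = se2**2 / ((v1 / x.size) ** 2 / (x.size - 1) + (v2 / y.size) ** 2 / (y.size - 1))
            assert res.t_stat == pytest.approx(t, abs=1e-12)
            assert res.df == pytest.approx(df, abs=1e-12)
            # independent route: scipy's implementation
            t_sp, p_sp = stats.ttest_ind(x, y, equal_var=False)
            assert res.t_stat == pytest.approx(t_sp, abs=1e-10)
            assert res.p_two_tail == pytest.approx(p_sp, abs=1e-10)

    def test_hand_sized_example(self):
        # n=3 each: worked by hand from the defining formulas
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 9.0])
        res = sp.welch_t(x, y)
        assert res.t_stat == pytest.approx((2 - 5) / np.sqrt(1 / 3 + 13 / 3), abs=1e-12)

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = sp.welch_t(x, x.copy())
        assert res.t_stat == 0.0 and res.p_two_tail == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sp.welch_t([1.0, 1.0], [1.0, 1.0])

    def test_p_two_tail_is_twice_one_tail(self):
        res = sp.welch_t([1.0, 2.0, 4.0], [5.0, 6.0, 9.0])
        assert res.p_two_tail == pytest.approx(2 * res.p_one_tail)
        assert res.df_int <= res.n_pre + res.n_post - 2


class TestWilcoxon:
    def test_rank_sum_identity_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            y = x + rng.normal(size=n) * rng.choice([0.1, 1.0])
            res = sp.wilcoxon_signed_rank(x, y)
            m = res.n_effective
            assert res.r_plus + res.r_minus == pytest.approx(m * (m + 1) / 2)

    def test_exact_all_improved_five_pairs(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        post = pre + np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        res = sp.wilcoxon_signed_rank(pre, post, method="exact")
        assert res.r_plus == 0 and res.r_minus == 15
        assert res.p_one_tail == pytest.approx(1 / 32)
        assert res.p_value == pytest.approx(2 / 32)

    def test_exact_distribution_against_enumeration(self):
        # m=6: enumerate all 64 sign patterns explicitly
        m = 6
        ranks = np.arange(1, m + 1)
        ws = [
            sum(r for r, bit in zip(ranks, f"{mask:06b}") if bit == "1")
            for mask in range(2**m)
        ]
        for w in range(0, 22):
            expected = sum(1 for v in ws if v <= w) / 64
            assert _exact_signed_rank_cdf(m, w) == pytest.approx(expected, abs=1e-12)

    def test_normal_approx_against_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = x + rng.normal(0.4, 1, size=25)
        ours = sp.wilcoxon_signed_rank(x, y, method="normal_approx_cc")
        # scipy applies the continuity correction and a tie correction; with
        # continuous data there are no ties, so the variants coincide
        ref = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_differences_dropped(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([1.0, 2.5, 2.0, 4.0])
        res = sp.wilcoxon_signed_rank(pre, post)
        assert res.n_effective == 2
        with pytest.raises(ValueError):
            sp.wilcoxon_signed_rank(pre, pre.copy())

    def test_exact_requires_untied_differences(self):
        pre = np.array([1.0, 2.0, 3.0])
        post = np.array([2.0, 3.0, 4.0])  # all |d| equal
        with pytest.raises(ValueError, match="untied"):
            sp.wilcoxon_signed_rank(pre, post, method="exact")


class TestBoxplot:
    def test_median_of_small_sample(self):
        bs = sp.boxplot_stats([1.0, 2.0, 3.0, 4.0, 5.0])
        assert bs.median == 3.0
        assert bs.lower_whisker == 1.0 and bs.upper_whisker == 5.0

    def test_ordering_invariant_and_whiskers_are_data_points(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 60)) * rng.choice([0.1, 1, 10])
            bs = sp.boxplot_stats(x)
            assert (
                bs.lower_whisker <= bs.lower_quartile <= bs.median
                <= bs.upper_quartile <= bs.upper_whisker
            )
            assert bs.lower_whisker in x and bs.upper_whisker in x
            iqr = bs.upper_quartile - bs.lower_quartile
            for o in bs.outliers:
                assert o < bs.lower_quartile - 1.5 * iqr or o > bs.upper_quartile + 1.5 * iqr

    def test_outliers_flagged_beyond_fences(self, reference_cohort):
        bs_pre = sp.boxplot_stats(reference_cohort.pre)
        bs_post = sp.boxplot_stats(reference_cohort.post)
        assert bs_pre.outliers == (0.585,)
        assert bs_post.outliers == (1.0,)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            sp.boxplot_stats([1.0, 2.0, 3.0])


class TestImprovementFraction:
    def test_toy_tables(self):
        t = sp.CohortTable.from_values(list("abcd"), [0.2, 0.3, 0.1, 0.5], [0.3, 0.2, 0.3, 0.5])
        assert sp.improvement_fraction(t) == pytest.approx(50.0)
        worse = sp.CohortTable.from_values(list("ab"), [0.4, 0.5], [0.3, 0.2])
        assert sp.improvement_fraction(worse) == 0.0

    def test_invariant_under_reordering(self, reference_cohort):
        shuffled = sp.CohortTable(reference_cohort.frame.sample(frac=1, random_state=0))
        assert sp.improvement_fraction(shuffled) == sp.improvement_fraction(reference_cohort)


class TestCohortReport:
    def test_report_assembles_all_sections(self, reference_cohort):
        rep = sp.cohort_report(reference_cohort)
        d = rep.to_dict()
        assert d["n"] == 38
        assert set(d) >= {"pre", "post", "boxplot_pre", "boxplot_post",
                          "improvement_percent", "welch", "wilcoxon"}
        text = rep.render_text()
        assert "Welch" in text and "Wilcoxon" in text

    def test_single_subject_rejected(self):
        t = sp.CohortTable.from_values(["a"], [0.2], [0.3])
        with pytest.raises(ValueError):
            sp.cohort_report(t)

    def test_null_cohort_type_one_error_rate(self):
        # pre and post drawn from the same distribution: Welch should reject
        # at about the nominal 5% rate
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 500
        for _ in range(reps):
            t = sp.CohortTable.from_values(
                [f"s{i}" for i in range(20)],
                np.abs(rng.normal(0.3, 0.1, 20)),
                np.abs(rng.normal(0.3, 0.1, 20)),
            )
            if sp.cohort_report(t).welch.p_two_tail < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07
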