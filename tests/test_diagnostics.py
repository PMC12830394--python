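"""Statistical battery: ROC/Youden, ICC, Bland-Altman, rank tests, ANOVA, KS."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vmre import (auc_concordance, bland_altman, descriptive_by_stage,
                  dunn_posthoc, icc, kruskal_wallis, ks_normality,
                  one_way_anova, roc_analysis)
from vmre.diagnostics import kruskal_wallis_permutation_p
from vmre.errors import AnalysisError


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                           n_boot=50)
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.cutoff == 10  # lowest cutoff among perfect ones

    def test_uninformative_values(self):
        res = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1], n_boot=20)
        assert res.auc == pytest.approx(0.5)

    def test_interleaved_fixture_pairwise_oracle(self):
        # class0 = {1, 3}, class1 = {2, 4}: 3 of 4 pairs concordant
        res = roc_analysis([1, 3, 2, 4], [0, 0, 1, 1], n_boot=20)
        assert res.auc == pytest.approx(0.75, abs=1e-12)
        assert auc_concordance([1, 3, 2, 4], [0, 0, 1, 1]) == 0.75

    def test_trapezoid_equals_concordance_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            values = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(values, labels, n_boot=2)
            assert res.auc == pytest.approx(
                auc_concordance(values, labels), abs=1e-12)

    def test_cutoff_is_argmax_of_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 30))
            values = rng.normal(0, 1, n) + rng.integers(0, 2, n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(values, labels, n_boot=2)
            best_j = max(
                np.mean(values[labels == 1] >= c)
                + np.mean(values[labels == 0] < c) - 1
                for c in values)
            assert res.youden_j == pytest.approx(best_j, abs=1e-12)
            assert res.cutoff in values

    def test_confusion_metrics_consistent(self):
        res = roc_analysis([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1], n_boot=20)
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1)
        assert 0 <= res.accuracy <= 1

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        vals = [1, 2, 3, 4, 2.5, 3.5, 5, 6]
        labs = [0, 0, 0, 0, 1, 1, 1, 1]
        a = roc_analysis(vals, labs, seed=7)
        b = roc_analysis(vals, labs, seed=7)
        assert a.ci_auc == b.ci_auc
        assert a.ci_auc[0] <= a.auc <= a.ci_auc[1]


class TestICC:
    def test_identical_columns_is_one(self):
        X = np.array([[1., 1.], [2., 2.], [5., 5.], [3., 3.]])
        with pytest.warns(UserWarning, match="identical"):
            res = icc(X)
        assert res.icc == 1.0

    def test_hand_anova_fixture(self):
        # MSR = 12.458333, MSC = 1.125, MSE = 0.791667 -> ICC = 20/23
        X = np.array([[7., 9.], [5., 6.], [8., 7.], [2., 3.]])
        res = icc(X)
        assert res.icc == pytest.approx(20 / 23, abs=1e-12)

    def test_matches_pingouin_two_way_random_absolute(self, rng):
        pg = pytest.importorskip("pingouin")
        M = rng.normal(4, 1.3, (20, 1)) + rng.normal(0, 0.3, (20, 2))
        mine = icc(M)
        df = pd.DataFrame({"s": np.repeat(range(20), 2),
                           "r": list(range(2)) * 20, "y": M.ravel()})
        ref = pg.intraclass_corr(df, "s", "r", "y")
        row = ref[ref.Type.str.contains("A,1")].iloc[0]
        assert mine.icc == pytest.approx(row.ICC, abs=1e-10)
        assert mine.icc_ci[0] == pytest.approx(row.CI95[0], abs=5e-3)
        assert mine.icc_ci[1] == pytest.approx(row.CI95[1], abs=5e-3)

    def test_pure_noise_columns_near_zero(self, rng):
        X = rng.normal(0, 1, (500, 2))
        res = icc(X)
        assert abs(res.icc) < 0.15

    def test_shift_invariance_and_bound(self, rng):
        X = rng.normal(4, 1, (15, 2)) + rng.normal(0, 0.4, (15, 2))
        res = icc(X)
        shifted = icc(X + 100.0)
        assert res.icc == pytest.approx(shifted.icc, abs=1e-9)
        assert res.icc <= 1.0

    def test_shape_requirements(self):
        with pytest.raises(AnalysisError):
            icc(np.ones((2, 2)))
        with pytest.raises(AnalysisError):
            icc(np.ones((5, 1)))


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(3.0, 3.0), (4.0, 4.0)])
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0

    def test_hand_arithmetic_fixture(self):
        res = bland_altman([(1, 2), (2, 2), (3, 5)])
        assert res.mean_diff == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa == pytest.approx((-2.96, 0.96))
        assert res.loa_1sd == pytest.approx((-2.0, 0.0))

    def test_antisymmetry(self, rng):
        pairs = rng.normal(5, 1, (10, 2))
        a = bland_altman(pairs)
        b = bland_altman(pairs[:, ::-1])
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.sd_diff == pytest.approx(b.sd_diff)

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError):
            bland_altman([(1, 2)])


class TestKruskalDunn:
    def test_identical_groups_null(self):
        g = [1., 2., 3., 4., 5.]
        res = kruskal_wallis([g, list(g), list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            res = kruskal_wallis([[2., 2.], [2., 2.]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_permutation_oracle_matches_exact_enumeration(self):
        # exact p over all 1680 assignments of 9 obs to 3 groups is 0.8786
        # (computed by full enumeration for this fixture)
        rng = np.random.default_rng(3)
        groups = [rng.normal(t * 0.8, 1, 3) for t in range(3)]
        p = kruskal_wallis_permutation_p(groups, n_perm=100_000, seed=0)
        assert p == pytest.approx(0.8786, abs=0.005)

    def test_h_monotone_in_group_separation(self):
        base = np.array([1., 2., 3.])
        hs = [kruskal_wallis([base, base + d, base + 2 * d]).statistic
              for d in (0.0, 1.1, 2.2, 3.3)]
        assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_two_group_case_matches_rank_test(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        h = kruskal_wallis([a, b])
        # H for k=2 is the squared standardized Mann-Whitney statistic;
        # p-values agree with the chi-square(1) <-> normal equivalence
        u_p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert h.p_value == pytest.approx(u_p.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            kruskal_wallis([[1., 2.], []])

    def test_bonferroni_is_tenfold_capped_for_five_groups(self, rng):
        groups = [rng.normal(i, 1, 4) for i in range(5)]
        adjusted = dunn_posthoc(groups)
        assert len(adjusted) == 10
        assert all(0 <= p <= 1 for p in adjusted.values())

    def test_identical_groups_all_adjusted_one(self):
        g = [1., 2., 3.]
        adjusted = dunn_posthoc([list(g) for _ in range(5)])
        assert all(p == 1.0 for p in adjusted.values())

    def test_extreme_group_hand_rank_oracle(self):
        # mean ranks 3.1667/6/9.1667/7.6667/14; hand z for (F0-like, extreme)
        # pair = -2.982853, raw p = 0.0028558, x10 -> 0.028558
        groups = [[1., 2., 3.], [2., 3., 4.], [3., 4., 5.],
                  [2.5, 3.5, 4.5], [50., 60., 70.]]
        adjusted = dunn_posthoc(groups)
        assert adjusted[(0, 4)] == pytest.approx(0.028558, abs=1e-5)
        assert adjusted[(3, 4)] == pytest.approx(0.811902, abs=1e-5)
        small = [pair for pair, p in adjusted.items() if p < 0.05]
        assert small == [(0, 4)]


class TestANOVA:
    def test_equal_group_means_f_near_zero(self):
        res = one_way_anova([[1., 2., 3.], [2., 1., 3.], [3., 2., 1.]])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_three_group_fixture(self):
        # means 2/3/7, SSB = 42, SSW = 6 -> F = 21, p = 0.001953125
        res = one_way_anova([[1., 2., 3.], [2., 3., 4.], [6., 7., 8.]])
        assert res.statistic == pytest.approx(21.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.001953125, rel=1e-9)

    def test_two_group_f_is_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 6)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_zero_within_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            res = one_way_anova([[1., 1.], [2., 2.]])
        assert res.degenerate


class TestNormality:
    def test_gaussian_sample_not_rejected(self, rng):
        x = rng.normal(5, 2, 200)
        assert ks_normality(x, seed=1) > 0.05

    def test_skewed_sample_rejected(self, rng):
        x = rng.exponential(1.0, 200)
        assert ks_normality(x, seed=1) < 0.01

    def test_matches_statsmodels_lilliefors(self, rng):
        lilliefors = pytest.importorskip(
            "statsmodels.stats.diagnostic").lilliefors
        x = rng.normal(0, 1, 60) + 0.4 * rng.normal(0, 1, 60) ** 2
        p_mine = ks_normality(x, n_sim=4000, seed=3)
        _, p_ref = lilliefors(x, dist="norm")
        # statsmodels interpolates a lookup table; rough agreement suffices
        assert p_mine == pytest.approx(p_ref, abs=0.1)

    def test_constant_data_flagged(self):
        with pytest.raises(AnalysisError):
            ks_normality([3.0] * 10)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(0, 1, 40)
        assert ks_normality(x, seed=9) == ks_normality(x, seed=9)


class TestDescriptives:
    def test_hand_computed_five_value_stage(self):
        df = pd.DataFrame({"stage": ["F1"] * 5 + ["F2"],
                           "v": [1., 2., 3., 4., 10., 7.]})
        out = descriptive_by_stage(df, "v")
        row = out.loc["F1"]
        assert row["mean"] == pytest.approx(4.0)
        assert row["sd"] == pytest.approx(np.std([1, 2, 3, 4, 10], ddof=1))
        assert row["median"] == 3.0
        assert (row["min"], row["max"]) == (1.0, 10.0)
        assert row["q1"] == 2.0 and row["q3"] == 4.0

    def test_single_value_stage_degenerate(self):
        df = pd.DataFrame({"stage": ["F4"], "v": [6.1]})
        row = descriptive_by_stage(df, "v").loc["F4"]
        assert row["sd"] == 0.0
        assert row["q1"] == row["q3"] == row["median"] == 6.1

    def test_round_trips_through_csv(self, tmp_path, rng):
        df = pd.DataFrame({"stage": ["F0", "F0", "F1", "F1"],
                           "v": rng.uniform(2, 8, 4)})
        out = descriptive_by_stage(df, "v")
        path = tmp_path / "desc.csv"
        out.to_csv(path)
        back = pd.read_csv(path, index_col="stage")
        assert np.allclose(back.to_numpy(), out.to_numpy())
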