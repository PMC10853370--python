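import numpy as np
import pytest
from scipy import stats as sps

from alpskit import cohortstats as cs


class TestOneWayAnova:
    def test_identical_group_means(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = cs.one_way_anova(vals, groups)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_f_is_squared_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        f = cs.one_way_anova(np.concatenate([a, b]),
                             ["a"] * 12 + ["b"] * 15).f
        t = cs.two_sample_t(a, b).t
        assert f == pytest.approx(t**2, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            cs.one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_matches_scipy_on_random_instances(self):
        """p values agree with an independent reference implementation to
        1e-10 over 100 random three-group instances."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            gs = [rng.normal(rng.normal(), 1.0, rng.integers(3, 20))
                  for _ in range(3)]
            vals = np.concatenate(gs)
            labels = np.repeat(["a", "b", "c"], [len(g) for g in gs])
            res = cs.one_way_anova(vals, labels)
            ref_f, ref_p = sps.f_oneway(*gs)
            assert res.f == pytest.approx(ref_f, abs=1e-10)
            assert res.p == pytest.approx(ref_p, abs=1e-10)


class TestAnovaFromSummary:
    def test_equal_means_zero_f(self):
        res = cs.anova_from_summary([10, 12], [5.0, 5.0], [1.0, 2.0])
        assert res.f == 0.0

    def test_demographics_age_row(self):
        """The three-group age summaries (n, mean, SD) =
        (35, 46.71, 9.02), (58, 43.95, 8.43), (16, 49.19, 10.04)
        reproduce F = 2.59 and p = 0.079."""
        res = cs.anova_from_summary(
            [35, 58, 16], [46.71, 43.95, 49.19], [9.02, 8.43, 10.04]
        )
        assert res.f == pytest.approx(2.59, abs=0.005)
        assert res.p == pytest.approx(0.079, abs=0.001)

    def test_summary_equals_raw_data_anova(self):
        """Raw-data ANOVA on samples constructed with exact means/SDs
        reproduces the summary ANOVA exactly."""
        rng = np.random.default_rng(3)
        gs, ns, means, sds = [], [], [], []
        for n in (8, 13, 21):
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)
            x = 2.0 + 1.5 * x + rng.normal()  # arbitrary location
            gs.append(x)
            ns.append(n)
            means.append(x.mean())
            sds.append(x.std(ddof=1))
        raw = cs.one_way_anova(
            np.concatenate(gs), np.repeat(["a", "b", "c"], ns)
        )
        summ = cs.anova_from_summary(ns, means, sds)
        assert raw.f == pytest.approx(summ.f, rel=1e-10)
        assert raw.p == pytest.approx(summ.p, rel=1e-10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cs.anova_from_summary([5, 5], [1.0, 2.0], [1.0, -0.1])


class TestLsdPosthoc:
    def test_two_groups_reduces_to_pooled_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 14)
        lsd = cs.lsd_posthoc(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 14)
        t = cs.two_sample_t(a, b)
        assert len(lsd) == 1
        assert lsd[0].t == pytest.approx(t.t, rel=1e-12)
        assert lsd[0].p == pytest.approx(t.p, rel=1e-12)

    def test_shifted_group_has_smallest_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(2.5, 1, 30)
        vals = np.concatenate([a, b, c])
        labels = np.repeat(["a", "b", "c"], 30)
        lsd = {frozenset((r.group_a, r.group_b)): r.p
               for r in cs.lsd_posthoc(vals, labels)}
        assert lsd[frozenset(("a", "c"))] < lsd[frozenset(("a", "b"))]
        assert lsd[frozenset(("b", "c"))] < lsd[frozenset(("a", "b"))]

    def test_null_per_comparison_type_i_rate(self):
        """Monte-Carlo under the null (three equal groups, 1000 reps): the
        per-comparison rejection rate at alpha 0.05 stays within +-0.02 —
        LSD applies no multiplicity correction by definition."""
        rng = np.random.default_rng(6)
        labels = np.repeat(["a", "b", "c"], 15)
        hits = 0
        total = 0
        for _ in range(1000):
            vals = rng.standard_normal(45)
            for r in cs.lsd_posthoc(vals, labels):
                hits += r.p < 0.05
                total += 1
        rate = hits / total
        assert abs(rate - 0.05) < 0.02


class TestTwoSampleT:
    def test_identical_samples(self):
        res = cs.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = cs.two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert abs(res.t) == pytest.approx(1.2247, abs=1e-4)
        assert res.df == 4

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1.5, rng.integers(2, 25))
            b = rng.normal(0.3, 1.0, rng.integers(2, 25))
            res = cs.two_sample_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.two_sample_t([1.0], [2.0, 3.0])


class TestPearsonFisher:
    def test_reconstructed_intervals_from_printed_r_and_n(self):
        """Fisher-z CIs at n = 38 reproduce the printed dose-correlation
        bounds for r = -0.472 and r = -0.460."""
        lo, hi = cs.ci_from_r_n(-0.472, 38)
        assert lo == pytest.approx(-0.688, abs=5e-4)
        assert hi == pytest.approx(-0.179, abs=5e-4)
        lo2, hi2 = cs.ci_from_r_n(-0.460, 38)
        assert lo2 == pytest.approx(-0.680, abs=5e-4)
        # upper bound sits on the print-rounding boundary (-0.16451)
        assert hi2 == pytest.approx(-0.164, abs=1e-3)

    def test_zero_r_interval_symmetric(self):
        lo, hi = cs.ci_from_r_n(0.0, 40)
        assert lo == pytest.approx(-hi, rel=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = cs.pearson_fisher_ci(x, -x)
        assert res.r == -1.0
        assert res.p == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cs.pearson_fisher_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            x = rng.standard_normal(n)
            y = 0.4 * x + rng.standard_normal(n)
            res = cs.pearson_fisher_ci(x, y)
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        rows = np.outer([10, 20], [30, 70]) / 10.0
        res = cs.chi_square_test(rows)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_demographics_sex_row(self):
        """Sex counts [[26, 45, 15], [9, 13, 1]] give p = 0.269 (with a
        small-expected-cell warning: the RE+ female cell expects < 5)."""
        with pytest.warns(UserWarning, match="expected cell"):
            res = cs.chi_square_test([[26, 45, 15], [9, 13, 1]])
        assert res.df == 2
        assert res.p == pytest.approx(0.269, abs=0.001)

    def test_perfect_association_2x2(self):
        res = cs.chi_square_test([[10, 0], [0, 10]])
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            cs.chi_square_test([[0, 0], [5, 5]])

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            table = rng.integers(5, 60, (rng.integers(2, 4), rng.integers(2, 4)))
            res = cs.chi_square_test(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert res.chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


def _mw_auc(pos, neg):
    """Exhaustive pairwise Mann-Whitney oracle with ties counted 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAndYouden:
    def test_perfect_separation(self):
        scores = [0.9, 1.0, 1.1, 1.5, 1.6, 1.7]
        labels = ["pos"] * 3 + ["neg"] * 3
        curve = cs.roc_curve(scores, labels, "pos", "lower-positive")
        assert cs.auc_trapezoid(curve) == pytest.approx(1.0)
        y = cs.youden_optimal_cutoff(curve)
        assert y.j == pytest.approx(1.0)
        assert y.sensitivity == 1.0 and y.specificity == 1.0
        assert 1.1 <= y.cutoff <= 1.5

    def test_degenerate_operating_points_present(self):
        curve = cs.roc_curve([1.0, 2.0, 3.0, 4.0], ["p", "n", "p", "n"],
                             "p", "lower-positive")
        pts = set(zip(curve.sensitivity.tolist(), curve.specificity.tolist()))
        assert (0.0, 1.0) in pts and (1.0, 0.0) in pts

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(10)
        n = 10_000
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, n)
        curve = cs.roc_curve(scores, labels, 1, "lower-positive")
        assert cs.auc_trapezoid(curve) == pytest.approx(0.5, abs=0.02)
        y = cs.youden_optimal_cutoff(curve)
        assert y.j < 0.05

    def test_orientation_flip_mirrors_auc(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        lo = cs.auc_trapezoid(cs.roc_curve(scores, labels, 1, "lower-positive"))
        hi = cs.auc_trapezoid(cs.roc_curve(scores, labels, 1, "higher-positive"))
        assert lo == pytest.approx(1.0 - hi, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cs.roc_curve([1.0, 2.0], ["p", "p"], "p")

    def test_tied_scores_hand_example(self):
        """negatives {1,2,3}, positives {2,3,4}, higher-positive: 9 pairs
        give (1 + 0.5) + (2 + 0.5) + 3 = 7 wins -> AUC 7/9."""
        scores = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        labels = ["n", "n", "n", "p", "p", "p"]
        curve = cs.roc_curve(scores, labels, "p", "higher-positive")
        assert cs.auc_trapezoid(curve) == pytest.approx(7 / 9, rel=1e-12)

    def test_auc_equals_mann_whitney_oracle(self):
        """Trapezoidal AUC is exactly the pairwise Mann-Whitney probability
        (ties 1/2) on random instances with n <= 50, including ties."""
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            curve = cs.roc_curve(scores, labels, 1, "higher-positive")
            auc = cs.auc_trapezoid(curve)
            oracle = _mw_auc(scores[labels == 1], scores[labels == 0])
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(10, 80))
            scores = rng.standard_normal(n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            curve = cs.roc_curve(scores, labels, 1, "higher-positive")
            assert cs.auc_trapezoid(curve) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_youden_maximizes_sens_plus_spec_minus_one(self):
        rng = np.random.default_rng(14)
        scores = rng.standard_normal(40)
        labels = (scores + rng.standard_normal(40) < 0).astype(int)
        curve = cs.roc_curve(scores, labels, 1, "lower-positive")
        y = cs.youden_optimal_cutoff(curve)
        assert y.j == pytest.approx(y.sensitivity + y.specificity - 1.0)
        assert y.j == pytest.approx(
            float((curve.sensitivity + curve.specificity - 1.0).max())
        )

    def test_auc_grading_bands(self):
        assert cs.auc_category(0.95) == "excellent"
        assert cs.auc_category(0.706) == "good"
        assert cs.auc_category(0.65) == "fair"
        assert cs.auc_category(0.5) == "poor"
        with pytest.raises(ValueError):
            cs.auc_category(1.2)
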