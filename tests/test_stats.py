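import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from kneedeg import stats_eval as SE


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBlandAltman:
    def test_identical_arms(self):
        ba = SE.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba["mean_diff"] == 0.0
        assert ba["lower_limit"] == 0.0 and ba["upper_limit"] == 0.0

    def test_constant_offset(self):
        ba = SE.bland_altman([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert ba["mean_diff"] == pytest.approx(-3.0)
        assert ba["sd_diff"] == 0.0

    def test_hand_computed_example(self):
        ba = SE.bland_altman([1, 2, 3], [1, 1, 1])
        assert ba["mean_diff"] == pytest.approx(1.0)
        assert ba["sd_diff"] == pytest.approx(1.0)
        assert ba["lower_limit"] == pytest.approx(-0.96)
        assert ba["upper_limit"] == pytest.approx(2.96)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            SE.bland_altman([1.0], [1.0])


class TestAUC:
    def test_perfect_separation(self):
        assert SE.roc_auc([1, 2, 10, 11], [0, 0, 1, 1])["auc"] == 1.0

    def test_all_ties(self):
        assert SE.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])["auc"] == 0.5

    def test_one_swap(self):
        assert SE.roc_auc([1, 2, 3, 4], [0, 1, 0, 1])["auc"] == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            SE.roc_auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        scores = np.round(rng.normal(size=n), 1)   # provoke ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert SE.roc_auc(scores, labels)["auc"] == pytest.approx(
            brute_force_auc(scores, labels))

    def test_equals_mannwhitney_U_over_n1n2(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        n1 = labels.sum()
        n0 = len(labels) - n1
        U = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        assert SE.roc_auc(scores, labels)["auc"] == pytest.approx(U / (n1 * n0))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.1, 5.0, 25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        a1 = SE.roc_auc(scores, labels)["auc"]
        a2 = SE.roc_auc(np.log(scores) * 3 + 2, labels)["auc"]
        assert a1 == pytest.approx(a2)


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        out = SE.group_tests(g)
        assert out.iloc[0]["p"] > 0.9

    def test_exact_small_sample_p(self):
        out = SE.group_tests({"a": [1, 2, 3], "b": [10, 11, 12]})
        row = out.iloc[0]
        assert row["stat"] == 0.0
        assert row["p"] == pytest.approx(0.1)
        assert row["flag"] == ""

    def test_wilcoxon_degenerate_flag(self):
        out = SE.group_tests({}, {"arm": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])})
        assert bool(out.iloc[0]["degenerate"])

    def test_significance_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(4, 1, 40)
        out = SE.group_tests({"a": a, "b": b})
        assert out.iloc[0]["flag"] == "**"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            SE.group_tests({"a": [1.0], "b": [1.0, 2.0]})


class TestScalingRegression:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 1.1, 1.2, 1.3])
        assert SE.scaling_regression(2 * x + 1, x)["r2"] == pytest.approx(1.0)

    def test_constant_scaling_flagged_undefined(self):
        out = SE.scaling_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert not out["defined"]
        assert np.isnan(out["r2"])

    def test_hand_computed_pearson(self):
        # r = 11 / sqrt(5 * 26) -> R^2 = 121/130
        out = SE.scaling_regression([2.0, 4.0, 5.0, 9.0], [1.0, 2.0, 3.0, 4.0])
        assert out["r2"] == pytest.approx(121.0 / 130.0, abs=1e-12)
        assert out["sign"] == 1.0

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            SE.scaling_regression([1.0, 2.0], [1.0, 2.0])
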