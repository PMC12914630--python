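import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evsecretome import (TestPolicy, compare, fold_change, kruskal_wallis,
                         mann_whitney_u, shapiro_wilk, summarize)
from conftest import exact_mann_whitney_p


class TestSummarize:
    @pytest.mark.parametrize("values, median, iqr", [
        ([1, 2, 3, 4, 5], 3.0, 2.0),
        ([1, 2, 3, 4], 2.5, 1.5),  # type-7 linear interpolation
        ([7, 7, 7], 7.0, 0.0),
    ])
    def test_known_values(self, values, median, iqr):
        s = summarize(values)
        assert s.median == pytest.approx(median)
        assert s.iqr == pytest.approx(iqr)
        assert s.p10 <= s.median <= s.p90

    def test_constant_whiskers(self):
        s = summarize([4.2] * 9)
        assert s.p10 == s.p90 == s.median == 4.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestFoldChange:
    @pytest.mark.parametrize("a, b, fold, direction", [
        (6.69e6, 4.02e6, 1.66, "decrease"),
        (3.43e5, 1.56e6, 4.55, "increase"),
        (5.0, 5.0, 1.00, "none"),
    ])
    def test_worked_examples(self, a, b, fold, direction):
        fc = fold_change(a, b)
        assert fc.fold == pytest.approx(fold, abs=0.005)
        assert fc.direction == direction

    def test_zero_median_flagged_not_raised(self):
        fc = fold_change(0.0, 5.0)
        assert not fc.defined and math.isnan(fc.fold)

    def test_half_up_rounding(self):
        assert fold_change(1.0, 1.125).fold == 1.13
        assert fold_change(1.0, 1.25, decimals=1).fold == 1.3

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.1, 1e9), st.floats(0.1, 1e9))
    def test_symmetric_with_flipped_direction(self, a, b):
        f1, f2 = fold_change(a, b), fold_change(b, a)
        assert f1.fold == f2.fold
        flip = {"increase": "decrease", "decrease": "increase", "none": "none"}
        assert f2.direction == flip[f1.direction]


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert u == 9.0  # all 9 pairs favour the first group
        assert p == pytest.approx(0.1)  # exact: 2 * 1/C(6,3)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_swap_antisymmetry(self):
        a, b = [1.5, 3.2, 7.7, 9.0], [2.2, 4.4, 5.5]
        ua, pa = mann_whitney_u(a, b)
        ub, pb = mann_whitney_u(b, a)
        assert ua + ub == len(a) * len(b)
        assert pa == pytest.approx(pb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    @settings(derandomize=True, max_examples=150)
    @given(st.sets(st.integers(-1000, 1000), min_size=2, max_size=10), st.data())
    def test_exact_p_matches_enumeration_oracle(self, values, data):
        values = data.draw(st.permutations(sorted(values)))
        na = data.draw(st.integers(1, len(values) - 1))
        a, b = values[:na], values[na:]
        u_imp, p_imp = mann_whitney_u(a, b)
        u_orc, p_orc = exact_mann_whitney_p(a, b)
        assert u_imp == u_orc
        assert p_imp == pytest.approx(p_orc, abs=1e-12)


class TestShapiroWilk:
    def test_three_point_symmetric_sample_is_perfectly_normal(self):
        w, _ = shapiro_wilk([-1, 0, 1])
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        w1, _ = shapiro_wilk(x)
        w2, _ = shapiro_wilk(5.0 - 2.5 * x)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_skew_lowers_w(self):
        even = np.linspace(0, 1, 20)
        skew = np.exp(np.linspace(0, 5, 20))
        assert shapiro_wilk(skew)[0] < shapiro_wilk(even)[0]

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1, 2])


class TestKruskalWallis:
    def test_hand_rank_statistic(self):
        # rank sums 3, 7, 11 -> H = 12/(6*7)*(9/2 + 49/2 + 121/2) - 21 = 32/7
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)

    def test_exact_mode_fully_separated(self):
        # only the 3! fully separated partitions of 90 reach the observed H
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]], method="exact")
        assert h == pytest.approx(32 / 7)
        assert p == pytest.approx(6 / 90)

    def test_all_constant_groups(self):
        h, p = kruskal_wallis([[2, 2], [2, 2, 2], [2]])
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_two_group_significance_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(2, 1, 12)
        _, p_kw = kruskal_wallis([a, b])
        _, p_mw = mann_whitney_u(a, b)
        assert (p_kw < 0.05) == (p_mw < 0.05)


class TestCompare:
    def test_gate_routes_normal_data_to_t_test(self):
        rng = np.random.default_rng(0)
        res = compare(rng.normal(size=21), rng.normal(size=21))
        assert res.test_used == "t_unpaired"

    def test_gate_routes_skewed_data_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        res = compare(rng.lognormal(0, 1.5, 21), rng.lognormal(0, 1.5, 21))
        assert res.test_used == "mann_whitney"

    def test_gate_off_always_mann_whitney(self):
        rng = np.random.default_rng(1)
        res = compare(rng.normal(size=21), rng.normal(size=21),
                      TestPolicy(use_normality_gate=False))
        assert res.test_used == "mann_whitney"

    def test_significance_threshold_and_bonferroni(self):
        # strongly separated groups: tiny p
        res = compare([1, 2, 3, 4, 5], [10, 11, 12, 13, 14],
                      TestPolicy(alpha=0.05, bonferroni_m=5, use_normality_gate=False))
        assert res.alpha == pytest.approx(0.01)
        assert res.significant == (res.p_value < 0.01)
        # p about 0.02 is not significant at the adjusted level 0.01
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
            r = compare(a, b, TestPolicy(alpha=0.05, bonferroni_m=5))
            if 0.01 < r.p_value < 0.05:
                assert not r.significant
                break
        else:
            pytest.fail("no case with p between 0.01 and 0.05 found")

    def test_result_contains_summaries_and_fold(self):
        res = compare([1, 2, 3, 4], [2, 4, 6, 8], labels=("pre", "post"))
        assert res.group_labels == ("pre", "post")
        assert res.summaries[0].n == 4
        assert res.fold_change.fold == pytest.approx(2.0)
        assert res.fold_change.direction == "increase"
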