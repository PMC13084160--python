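"""The inferential battery against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ncfish.stats import (adjust_pvalues, chi_squared, compare_groups,
                          dunn_posthoc, kruskal_wallis, rank_sum_and_t,
                          significance_code)


def _ranks(values):
    """Independent average-rank computation by explicit sorting."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestKruskalWallis:
    def test_hand_computed_example(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p = kruskal_wallis(vals, groups)
        assert h == pytest.approx(7.2)

    def test_all_equal_degenerates_to_zero(self):
        h, p = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_with_ties(self, rng):
        vals = rng.integers(0, 6, size=30).astype(float)
        groups = rng.integers(0, 3, size=30)
        if len(set(groups)) < 3 or len(set(vals)) < 2:
            vals[:3] = [0, 1, 2]
            groups[:3] = [0, 1, 2]
        h, p = kruskal_wallis(vals, groups)
        h2, p2 = sps.kruskal(*[vals[groups == g] for g in np.unique(groups)])
        assert h == pytest.approx(h2, abs=1e-9)
        assert p == pytest.approx(p2, abs=1e-9)

    def test_two_group_equals_ranksum_z_squared(self):
        # no ties: H = z^2 of the normal-approximation rank-sum test
        a = [1.2, 3.4, 5.1, 7.7, 2.2, 9.9, 11.0, 12.5, 0.5, 4.4, 6.6]
        b = [2.1, 3.3, 8.8, 10.1, 13.7, 1.1, 5.5, 6.1, 7.1, 14.2]
        h, _ = kruskal_wallis(a + b, ["a"] * len(a) + ["b"] * len(b))
        w = sum(_ranks(a + b)[: len(a)])
        n1, n2, n = len(a), len(b), len(a) + len(b)
        z = (w - n1 * (n + 1) / 2) / math.sqrt(n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(z ** 2, abs=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a"] * 3)


class TestDunn:
    def test_identical_groups_z_zero(self):
        df = dunn_posthoc([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3,
                          correction="none")
        assert df["z"].iloc[0] == pytest.approx(0.0)
        assert df["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_matches_rank_arithmetic_oracle(self, rng):
        vals = rng.normal(size=18).tolist()
        groups = ["a"] * 5 + ["b"] * 6 + ["c"] * 7
        df = dunn_posthoc(vals, groups, correction="none")

        ranks = _ranks(vals)
        n = len(vals)
        means = {}
        sizes = {}
        for g in ("a", "b", "c"):
            idx = [i for i, gg in enumerate(groups) if gg == g]
            means[g] = sum(ranks[i] for i in idx) / len(idx)
            sizes[g] = len(idx)
        for _, row in df.iterrows():
            a, b = row["group_a"], row["group_b"]
            se = math.sqrt((n * (n + 1) / 12.0)
                           * (1 / sizes[a] + 1 / sizes[b]))
            z = (means[a] - means[b]) / se
            assert row["z"] == pytest.approx(z, abs=1e-9)
            assert row["p_raw"] == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-9)

    def test_k2_matches_ranksum_normal_approx(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.8, size=15)
        df = dunn_posthoc(np.concatenate([a, b]),
                          ["a"] * 12 + ["b"] * 15, correction="none")
        w, _ = rank_sum_and_t(a, b, kind="wilcoxon")
        n1, n2, n = 12, 15, 27
        z_rs = (w - n1 * (n + 1) / 2) / math.sqrt(n1 * n2 * (n + 1) / 12)
        assert abs(abs(df["z"].iloc[0]) - abs(z_rs)) < 1e-6

    def test_bonferroni_multiplies_by_pair_count(self, rng):
        vals = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        raw = dunn_posthoc(vals, groups, correction="none")
        bonf = dunn_posthoc(vals, groups, correction="bonferroni")
        np.testing.assert_allclose(bonf["p_adj"],
                                   np.minimum(raw["p_raw"] * 3, 1.0))

    def test_pair_count(self):
        df = dunn_posthoc(list(range(20)), [g for g in "abcd" for _ in range(5)])
        assert len(df) == 4 * 3 // 2


class TestAdjustPvalues:
    def test_bonferroni_worked(self):
        assert adjust_pvalues([0.01, 0.02, 0.04], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.12])

    def test_holm_worked(self):
        # step-down: [3*0.01, max(0.03, 2*0.02), max(0.04, 1*0.04)]
        assert adjust_pvalues([0.01, 0.02, 0.04], "holm") == pytest.approx(
            [0.03, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        assert adjust_pvalues([0.031], "bh") == pytest.approx([0.031])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=12)
        for ours, theirs in (("bonferroni", "bonferroni"), ("holm", "holm"),
                             ("bh", "fdr_bh")):
            np.testing.assert_allclose(adjust_pvalues(p.tolist(), ours),
                                       multipletests(p, method=theirs)[1],
                                       atol=1e-12)

    def test_bonferroni_idempotent_after_clipping(self):
        p = [0.5, 0.9, 0.99]
        once = adjust_pvalues(p, "bonferroni")
        # values already clipped at 1 stay at 1
        assert adjust_pvalues(once, "bonferroni") == [1.0, 1.0, 1.0]

    def test_adjusted_at_least_raw_for_fwer_methods(self, rng):
        p = rng.uniform(size=8).tolist()
        for m in ("bonferroni", "holm"):
            adj = adjust_pvalues(p, m)
            assert all(a >= r - 1e-12 for a, r in zip(adj, p))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "holm")


class TestRankSum:
    def test_identical_samples_p_one(self):
        a = [1.5, 2.5, 3.5]
        w, p = rank_sum_and_t(a, a, kind="wilcoxon")
        assert p == pytest.approx(1.0)

    def test_exact_extreme_case(self):
        # {1,2,3} vs {4,5,6}: W = 6 is the unique minimum; two-sided
        # p = 2 * (1/20) = 0.1 by full enumeration of C(6,3) subsets
        w, p = rank_sum_and_t([1, 2, 3], [4, 5, 6], kind="wilcoxon")
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_scipy_enumeration(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        _, p = rank_sum_and_t(a, b, kind="wilcoxon")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_large_sample_matches_scipy_normal_approx(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        _, p = rank_sum_and_t(a, b, kind="wilcoxon")
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert p == pytest.approx(res.pvalue, abs=1e-9)

    def test_welch_t(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(loc=1.0, scale=2.0, size=14)
        t, p = rank_sum_and_t(a, b, kind="t")
        t2, p2 = sps.ttest_ind(a, b, equal_var=False)
        assert (t, p) == pytest.approx((t2, p2))

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            rank_sum_and_t([1.0, 1.0], [1.0, 1.0], kind="t")

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            rank_sum_and_t([], [1.0], kind="wilcoxon")


class TestChiSquared:
    def test_balanced_table_zero(self):
        x2, p = chi_squared([[10, 10], [10, 10]])
        assert x2 == 0.0 and p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self, rng):
        obs = rng.integers(1, 40, size=(3, 4)).astype(float)
        x2, p = chi_squared(obs)
        total = obs.sum()
        acc = 0.0
        for i in range(3):
            for j in range(4):
                e = obs[i].sum() * obs[:, j].sum() / total
                acc += (obs[i, j] - e) ** 2 / e
        assert x2 == pytest.approx(acc, abs=1e-9)
        x2s, ps, _, _ = sps.chi2_contingency(obs, correction=False)
        assert x2 == pytest.approx(x2s, abs=1e-9)
        assert p == pytest.approx(ps, abs=1e-9)

    def test_homogeneity_under_scaling(self):
        t = np.array([[20.0, 10.0], [10.0, 20.0]])
        x2a, _ = chi_squared(t)
        x2b, _ = chi_squared(3 * t)
        assert x2b == pytest.approx(3 * x2a)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 5]])


class TestCalibration:
    def test_type_one_error_rank_sum_and_kw(self):
        """Null rejection rate at alpha=0.05 within [0.035, 0.065]."""
        rng = np.random.default_rng(123)
        n_sim = 500  # the acceptance suite runs the full 2000
        rej_rs = rej_kw = 0
        for _ in range(n_sim):
            a, b = rng.normal(size=20), rng.normal(size=20)
            rej_rs += rank_sum_and_t(a, b, kind="wilcoxon")[1] < 0.05
            vals = rng.normal(size=75)
            rej_kw += kruskal_wallis(vals, np.repeat([0, 1, 2], 25))[1] < 0.05
        assert 0.025 <= rej_rs / n_sim <= 0.075
        assert 0.025 <= rej_kw / n_sim <= 0.075


class TestCompareGroups:
    def test_separated_groups_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 10),
                               rng.normal(3, 0.1, 10),
                               rng.normal(6, 0.1, 10)])
        groups = np.repeat(["lo", "mid", "hi"], 10)
        res = compare_groups(vals, groups, posthoc="dunn", correction="bonferroni")
        assert res.p_value < 0.001
        assert len(res.posthoc) == 3
        d = res.to_dict()
        assert d["significance"] in ("***", "****")

    def test_pairwise_wilcoxon_posthoc(self, rng):
        vals = np.concatenate([rng.normal(size=8), rng.normal(size=8),
                               rng.normal(size=8)])
        groups = np.repeat(["a", "b", "c"], 8)
        res = compare_groups(vals, groups, posthoc="pairwise-wilcoxon",
                             correction="holm")
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-12).all()

    def test_significance_codes(self):
        assert significance_code(0.2) == "NS"
        assert significance_code(0.04) == "*"
        assert significance_code(0.004) == "**"
        assert significance_code(4e-4) == "***"
        assert significance_code(4e-5) == "****"


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
@settings(deadline=None, max_examples=50)
def test_adjustment_outputs_stay_in_unit_interval(p):
    for m in ("bonferroni", "holm", "bh"):
        adj = adjust_pvalues(p, m)
        assert all(0.0 <= a <= 1.0 for a in adj)
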