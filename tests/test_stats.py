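"""Exact nonparametric tests against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from benthochange import (
    adjust_pvalues,
    dunn_posthoc,
    kruskal_wallis,
    rank_sum_test,
    signed_rank_test,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_signed_rank_p(diffs, alternative):
    """Enumerate all 2^n sign assignments of the midranks of |d| (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    stats = np.asarray(stats)
    p_ge = np.mean(stats >= w_obs - 1e-9)
    p_le = np.mean(stats <= w_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def brute_rank_sum_p(a, b, alternative):
    """Enumerate all C(n, n_a) group assignments of the pooled midranks."""
    pooled = np.concatenate([a, b]).astype(float)
    ranks = sps.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    w_obs = ranks[:n_a].sum()
    stats = np.asarray([sum(ranks[i] for i in comb)
                        for comb in itertools.combinations(range(n), n_a)])
    p_ge = np.mean(stats >= w_obs - 1e-9)
    p_le = np.mean(stats <= w_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


# ---------------------------------------------------------------------------
# Signed-rank test
# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_all_positive_small_sample(self):
        res = signed_rank_test([3, 5, 7], alternative="greater")
        assert res.p_value == pytest.approx(1 / 8)
        assert res.exact and res.n_effective == 3

    def test_zeros_dropped_before_ranking(self):
        res = signed_rank_test([0, 2, 4], alternative="greater")
        assert res.n_effective == 2
        assert res.p_value == pytest.approx(1 / 4)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            signed_rank_test([0, 0, 0])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_matches_brute_force_with_ties(self, alternative, rng):
        for _ in range(30):
            n = rng.integers(2, 11)
            d = rng.integers(-3, 4, n).astype(float)  # tie-rich, with zeros
            if np.all(d == 0):
                continue
            res = signed_rank_test(d, alternative=alternative)
            assert res.p_value == pytest.approx(
                brute_signed_rank_p(d, alternative), abs=1e-12)

    def test_tie_free_exact_matches_scipy(self, rng):
        d = rng.normal(size=12)
        ours = signed_rank_test(d, alternative="two_sided")
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_threshold(self, rng):
        d = rng.normal(0.3, 1.0, 25)
        exact = signed_rank_test(d, "greater", exact_threshold=30)
        approx = signed_rank_test(d, "greater", exact_threshold=10)
        assert exact.exact and not approx.exact
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15, abs=0.01)


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_fully_separated_samples(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.exact

    def test_identical_samples_two_sided_p_one(self):
        res = rank_sum_test([1, 2, 1], [1, 2, 1], alternative="two_sided")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_matches_brute_force_with_ties(self, alternative, rng):
        for _ in range(30):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 6))
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
            res = rank_sum_test(a, b, alternative=alternative)
            assert res.p_value == pytest.approx(
                brute_rank_sum_p(a, b, alternative), abs=1e-12)

    def test_tie_free_exact_matches_scipy(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        ours = rank_sum_test(a, b, alternative="two_sided")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)

    def test_degenerate_identical_data(self):
        res = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 1.0)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_small_instance_within_permutation_oracle_ci(self, rng):
        groups = [[1, 5, 7], [2, 2, 9], [8, 3, 1]]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups).astype(float)
        sizes = [len(g) for g in groups]
        n_shuffle = 20_000
        count = 0
        h_obs = res.statistic
        for _ in range(n_shuffle):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h = sps.kruskal(*parts).statistic
            if h >= h_obs - 1e-9:
                count += 1
        p_mc = count / n_shuffle
        se = np.sqrt(p_mc * (1 - p_mc) / n_shuffle)
        # chi-square approximation vs permutation truth: generous CI
        assert abs(res.p_value - p_mc) < 4 * se + 0.03

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])


class TestDunn:
    def test_identical_groups_z_zero_p_one(self):
        out = dunn_posthoc([[1, 1, 1], [1, 1, 1]])
        assert out["z"].iloc[0] == 0.0 and out["p_value"].iloc[0] == 1.0

    def test_three_groups_three_rows(self):
        out = dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        assert len(out) == 3

    def test_hand_computed_z(self):
        # no ties: base variance N(N+1)/12 = 3.5; mean ranks 1.5, 3.5, 5.5
        out = dunn_posthoc([[1, 2], [3, 4], [5, 6]], labels=["a", "b", "c"])
        z_ab = out[(out["level_a"] == "a") & (out["level_b"] == "b")]["z"].iloc[0]
        assert z_ab == pytest.approx((1.5 - 3.5) / np.sqrt(3.5 * (0.5 + 0.5)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2], []])


# ---------------------------------------------------------------------------
# Multiplicity adjustment
# ---------------------------------------------------------------------------

class TestAdjustPvalues:
    def test_bonferroni_multiplies_and_caps(self):
        assert adjust_pvalues([0.001], m=2) == [0.002]
        assert adjust_pvalues([0.6, 0.7]) == [1.0, 1.0]

    def test_holm_step_down_by_hand(self):
        assert adjust_pvalues([0.01, 0.04, 0.03], method="holm") == \
            pytest.approx([0.03, 0.06, 0.06])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_statsmodels_and_bonferroni_dominates_holm(self, p):
        from statsmodels.stats.multitest import multipletests

        bonf = adjust_pvalues(p, "bonferroni")
        holm = adjust_pvalues(p, "holm")
        assert np.allclose(bonf, multipletests(p, method="bonferroni")[1])
        assert np.allclose(holm, multipletests(p, method="holm")[1])
        assert all(b >= h - 1e-12 for b, h in zip(bonf, holm))


def test_one_sided_rejection_rate_conservative_under_null(rng):
    """Exact one-sided signed-rank test at alpha=0.05 under an exchangeable null."""
    n_rep, n = 2000, 12
    rejections = sum(
        signed_rank_test(rng.normal(size=n), "greater").p_value <= 0.05
        for _ in range(n_rep)
    )
    rate = rejections / n_rep
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert rate <= 0.05 + 3 * se
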