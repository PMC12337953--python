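"""ANOVA, Tukey HSD, pairwise Welch t, and the Pearson chi-squared test,
each checked against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from idpome.stats import chi_squared_test, one_way_anova, pairwise_t, tukey_hsd


def anova_oracle(groups):
    """Brute-force between/within sum-of-squares F ratio."""
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(pooled) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def chi2_oracle(table):
    """Brute-force Pearson statistic from first principles."""
    table = np.asarray(table, float)
    n = table.sum()
    chi2 = 0.0
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        e = table[i].sum() * table[:, j].sum() / n
        chi2 += (table[i, j] - e) ** 2 / e
    return chi2


class TestAnova:
    def test_hand_computed_f(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.f_stat == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_zero(self):
        res = one_way_anova([[1, 2, 3]] * 3)
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_match_squared_pooled_t(self):
        a, b = [1.0, 2.0, 4.0, 3.5], [2.5, 4.0, 5.0]
        res = one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2)

    def test_error_paths(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            one_way_anova([[2.0, 2.0], [2.0, 2.0]])

    @given(
        st.lists(
            st.lists(st.floats(-10, 10), min_size=2, max_size=8),
            min_size=2,
            max_size=5,
        )
    )
    def test_matches_sum_of_squares_oracle(self, groups):
        arrays = [np.asarray(g) for g in groups]
        if sum(a.var() for a in arrays) == 0:
            return
        res = one_way_anova(arrays)
        assert res.f_stat == pytest.approx(anova_oracle(arrays), rel=1e-10, abs=1e-10)


class TestTukey:
    def test_identical_groups_null(self):
        table = tukey_hsd([[1, 2, 3]] * 3)
        assert (table["mean_diff"] == 0).all()
        np.testing.assert_allclose(table["p_adj"], 1.0, atol=1e-6)

    def test_pair_count_and_label_symmetry(self):
        groups = [[1, 2, 3], [2, 3, 5], [0, 1, 1], [4, 5, 6]]
        table = tukey_hsd(groups, labels=list("abcd"))
        assert len(table) == 6
        swapped = tukey_hsd(groups[::-1], labels=list("dcba"))
        for _, row in table.iterrows():
            match = swapped[
                (swapped["group_a"] == row["group_b"]) & (swapped["group_b"] == row["group_a"])
            ]
            assert match["mean_diff"].item() == pytest.approx(-row["mean_diff"])
            assert match["p_adj"].item() == pytest.approx(row["p_adj"])


class TestPairwiseT:
    def test_hand_welch_t(self):
        table = pairwise_t([[1, 2, 3], [2, 3, 4]])
        assert abs(table["t"].item()) == pytest.approx(np.sqrt(1.5), rel=1e-6)

    def test_degenerate_variances(self):
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_t([[0, 0, 0], [1, 1, 1]])
        table = pairwise_t([[2, 2, 2], [2, 2, 2]])
        assert table["t"].item() == 0.0 and table["p"].item() == 1.0

    def test_bonferroni_adjustment(self):
        groups = [[1, 2, 3], [2, 3, 5], [9, 10, 11]]
        plain = pairwise_t(groups)
        adj = pairwise_t(groups, correction="bonferroni")
        np.testing.assert_allclose(
            adj["p_adj"], np.minimum(plain["p"] * len(plain), 1.0)
        )


class TestChiSquared:
    def test_hand_two_by_two(self):
        res = chi_squared_test([[10, 0], [0, 10]])
        assert res.chi2 == pytest.approx(20.0)
        assert res.dof == 1

    def test_identical_rows_give_zero(self):
        res = chi_squared_test([[5, 10, 5], [5, 10, 5]])
        assert res.chi2 == pytest.approx(0.0)

    def test_expected_margins_conserved(self):
        table = np.array([[12, 5, 9], [3, 14, 2], [7, 7, 7]], float)
        res = chi_squared_test(table)
        np.testing.assert_allclose(res.expected.sum(axis=1), table.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0), table.sum(axis=0))

    def test_permutation_invariance(self):
        table = np.array([[12, 5, 9], [3, 14, 2]], float)
        base = chi_squared_test(table).chi2
        assert chi_squared_test(table[::-1]).chi2 == pytest.approx(base)
        assert chi_squared_test(table[:, ::-1]).chi2 == pytest.approx(base)

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_count_scaling_homogeneity(self, k):
        table = np.array([[12, 5], [3, 14]], float)
        assert chi_squared_test(k * table).chi2 == pytest.approx(
            k * chi_squared_test(table).chi2
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_test([[1, 0], [2, 0]])

    @given(
        st.lists(
            st.lists(st.integers(1, 30), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_matches_brute_force_oracle(self, rows):
        table = np.asarray(rows, float)
        res = chi_squared_test(table)
        assert res.chi2 == pytest.approx(chi2_oracle(table), rel=1e-10)
        assert res.dof == (table.shape[0] - 1) * (table.shape[1] - 1)
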