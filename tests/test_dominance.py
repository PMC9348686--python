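"""Sociomatrix, dyadic signs, Kondo–Hurnik values and categorization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import herdrank as hr


def random_sociomatrix(rng, n):
    X = rng.integers(0, 6, size=(n, n))
    np.fill_diagonal(X, 0)
    labels = [str(100 + i) for i in range(n)]
    return hr.SocioMatrix(labels, X)


class TestSociomatrix:
    def test_counts_per_ordered_pair(self):
        lst = hr.InteractionList.from_pairs([("A", "B"), ("A", "B"), ("B", "A")])
        m = hr.sociomatrix(lst)
        f = m.to_frame()
        assert f.loc["A", "B"] == 2 and f.loc["B", "A"] == 1
        assert m.total() == 3

    def test_roster_only_animals_get_zero_rows(self):
        m = hr.sociomatrix(hr.InteractionList(), roster={"A", "B"})
        assert m.labels == ["A", "B"] and m.total() == 0

    def test_total_equals_list_length_random(self):
        rng = np.random.default_rng(9)
        ids = [str(i) for i in range(5)]
        pairs = []
        while len(pairs) < 100:
            a, b = rng.choice(5, size=2, replace=False)
            pairs.append((ids[a], ids[b]))
        m = hr.sociomatrix(hr.InteractionList.from_pairs(pairs))
        assert m.total() == 100

    def test_numeric_ids_sort_numerically(self):
        lst = hr.InteractionList.from_pairs([("117", "9"), ("1021", "117")])
        assert hr.sociomatrix(lst).labels == ["9", "117", "1021"]

    def test_label_order_invariance_of_dyadic(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "A")]
        m1 = hr.sociomatrix(hr.InteractionList.from_pairs(pairs))
        m2 = hr.sociomatrix(hr.InteractionList.from_pairs(pairs[::-1]))
        assert hr.dyadic_matrix(m1) == hr.dyadic_matrix(m2)


class TestDyadicMatrix:
    @pytest.mark.parametrize(
        "xab, xba, expected",
        [(2, 1, 1), (1, 2, -1), (3, 3, 0), (0, 0, 0)],
    )
    def test_sign_of_count_difference(self, xab, xba, expected):
        m = hr.SocioMatrix(["A", "B"], np.array([[0, xab], [xba, 0]]))
        d = hr.dyadic_matrix(m)
        assert d.to_frame().loc["A", "B"] == expected
        assert d.to_frame().loc["B", "A"] == -expected

    def test_antisymmetry_and_zero_sum_random(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            d = hr.dyadic_matrix(random_sociomatrix(rng, n))
            assert np.array_equal(d.values, -d.values.T)
            s = d.values.sum(axis=1)
            assert s.sum() == 0
            assert np.abs(s).max() <= n - 1

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(4)
        m = random_sociomatrix(rng, 6)
        perm = rng.permutation(6)
        m2 = hr.SocioMatrix(
            [m.labels[i] for i in perm], m.values[np.ix_(perm, perm)])
        d1 = hr.dyadic_matrix(m).to_frame()
        d2 = hr.dyadic_matrix(m2).to_frame()
        assert d2.loc[d1.index, d1.columns].equals(d1)


class TestDominanceValues:
    def test_strict_linear_order(self, linear_dyadic):
        t = hr.dominance_values(linear_dyadic)
        assert dict(zip(t.df.animal_id, t.df.dominance_value)) == {
            "A": 2, "B": 0, "C": -2}
        assert t.df["dominance_value"].sum() == 0
        assert list(t.df.dominance_value) == [-2, 0, 2]  # ascending

    def test_empty_matrix_gives_empty_table(self):
        d = hr.DyadicMatrix([], np.zeros((0, 0)))
        assert len(hr.dominance_values(d).df) == 0

    def test_category_columns_follow_flags(self, linear_dyadic):
        t = hr.dominance_values(linear_dyadic, with_rank=False)
        assert "social_rank" not in t.df.columns
        assert "social_hierarchy" in t.df.columns

    def test_categories_monotone_in_value(self):
        rng = np.random.default_rng(13)
        order = {"low": 0, "high": 1,
                 "subordinate": 0, "intermediate": 1, "dominant": 2}
        for _ in range(10):
            d = hr.dyadic_matrix(random_sociomatrix(rng, 10))
            t = hr.dominance_values(d).df  # sorted ascending by value
            for col in ("social_rank", "social_hierarchy"):
                codes = [order[c] for c in t[col]]
                assert codes == sorted(codes)


class TestCategorize:
    def test_half_split_on_wide_range(self):
        # range -26..19: width 46, half size 23 -> -4 low, -3 high
        values = list(range(-26, 20))
        cats = hr.categorize(values, 2)
        by_value = dict(zip(values, cats))
        # independent lattice enumeration of the 46-point range
        expected = {
            v: ("low" if (v - (-26)) // 23 < 1 else "high") for v in values}
        assert by_value == expected
        assert by_value[-4] == "low" and by_value[-3] == "high"

    def test_tertiles_with_fractional_bin_size(self):
        # range -2..2: 5 points, size 5/3; floor rule puts -2 | 0 | 2 apart
        assert hr.categorize([-2, 0, 2], 3) == [
            "subordinate", "intermediate", "dominant"]

    def test_tertile_floor_rule_matches_direct_evaluation(self):
        import math

        values = list(range(-26, 20))
        cats = hr.categorize(values, 3)
        size = 46 / 3
        labels = ("subordinate", "intermediate", "dominant")
        expected = [
            labels[min(2, math.floor((v + 26) / size))] for v in values]
        assert cats == expected

    def test_degenerate_range_single_animal(self, caplog):
        assert hr.categorize([0], 3) == ["intermediate"]
        assert hr.categorize([5, 5], 2) == ["low", "low"]

    def test_invalid_k_rejected(self):
        with pytest.raises(hr.ParameterError):
            hr.categorize([1, 2], 4)

    @given(
        st.lists(st.integers(min_value=-30, max_value=30), min_size=1,
                 max_size=40),
        st.sampled_from([2, 3]),
    )
    def test_monotone_property(self, values, k):
        cats = hr.categorize(values, k)
        rank = {lab: i for i, lab in enumerate(
            hr.dominance.RANK_LABELS if k == 2
            else hr.dominance.HIERARCHY_LABELS)}
        paired = sorted(zip(values, cats))
        codes = [rank[c] for _, c in paired]
        assert codes == sorted(codes)
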