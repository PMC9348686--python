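"""David's score, Elo ratings, and cross-method correlations."""

from __future__ import annotations

import numpy as np
import pytest

import herdrank as hr


def brute_force_davids(m: hr.SocioMatrix, variant="Pij"):
    """Independent per-element evaluation of DS = w + w2 - l - l2."""
    n = m.n
    X = m.values.astype(float)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nij = X[i, j] + X[j, i]
            if nij > 0:
                p = X[i, j] / nij
                if variant == "Dij":
                    p = p - (p - 0.5) / (nij + 1)
                P[i, j] = p
    ds = []
    for i in range(n):
        w = sum(P[i, j] for j in range(n))
        w2 = sum(P[i, j] * sum(P[j, k] for k in range(n)) for j in range(n))
        l = sum(P[j, i] for j in range(n))
        l2 = sum(P[j, i] * sum(P[k, j] for k in range(n)) for j in range(n))
        ds.append(w + w2 - l - l2)
    return np.array(ds)


class TestDavidsScore:
    def test_two_animal_hand_example(self):
        # A beats B 3-1: w=0.75, w2=0.1875, l=0.25, l2=0.1875 -> DS_A=0.5
        m = hr.SocioMatrix(["A", "B"], np.array([[0, 3], [1, 0]]))
        scores = hr.davids_score(m).series()
        assert scores["A"] == pytest.approx(0.5)
        assert scores["B"] == pytest.approx(-0.5)

    def test_symmetric_matrix_gives_all_zero(self):
        X = np.array([[0, 2, 5], [2, 0, 1], [5, 1, 0]])
        scores = hr.davids_score(hr.SocioMatrix(list("ABC"), X)).series()
        assert np.allclose(scores.to_numpy(), 0.0)

    @pytest.mark.parametrize("variant", ["Pij", "Dij"])
    def test_zero_sum_and_oracle_agreement(self, variant):
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(2, 10))
            X = rng.integers(0, 8, size=(n, n)) * (rng.random((n, n)) < 0.6)
            np.fill_diagonal(X, 0)
            m = hr.SocioMatrix([str(i) for i in range(n)], X)
            got = hr.davids_score(m, variant).series().to_numpy()
            assert got.sum() == pytest.approx(0.0, abs=1e-9)
            assert np.allclose(got, brute_force_davids(m, variant))

    def test_single_animal_is_domain_error(self):
        with pytest.raises(hr.ParameterError):
            hr.davids_score(hr.SocioMatrix(["A"], np.zeros((1, 1))))


class TestElo:
    def test_single_interaction_from_equal_ratings(self):
        lst = hr.InteractionList.from_pairs([("A", "B")])
        scores = hr.elo_rating(lst, k=100, start=1000).series()
        assert scores["A"] == pytest.approx(1050.0)
        assert scores["B"] == pytest.approx(950.0)

    def test_empty_list_with_roster_keeps_start(self):
        scores = hr.elo_rating(hr.InteractionList(), roster=["A", "B", "C"]
                               ).series()
        assert (scores == 1000.0).all()

    def test_total_rating_conserved(self):
        rng = np.random.default_rng(41)
        pairs = []
        ids = [str(i) for i in range(8)]
        for _ in range(300):
            a, b = rng.choice(8, size=2, replace=False)
            pairs.append((ids[a], ids[b]))
        scores = hr.elo_rating(hr.InteractionList.from_pairs(pairs)).series()
        assert scores.sum() == pytest.approx(8 * 1000.0)

    def test_update_magnitude_shrinks_for_expected_wins(self):
        # A beats B twice: the second gain is smaller than the first
        lst1 = hr.InteractionList.from_pairs([("A", "B")])
        lst2 = hr.InteractionList.from_pairs([("A", "B"), ("A", "B")])
        first = hr.elo_rating(lst1).series()["A"] - 1000.0
        second = hr.elo_rating(lst2).series()["A"] - \
            hr.elo_rating(lst1).series()["A"]
        assert 0 < second < first

    def test_order_dependence(self):
        a = hr.InteractionList.from_pairs([("A", "B"), ("B", "C")])
        b = hr.InteractionList.from_pairs([("B", "C"), ("A", "B")])
        sa = hr.elo_rating(a).series()
        sb = hr.elo_rating(b).series()
        assert not np.allclose(sa.to_numpy(), sb[sa.index].to_numpy())


class TestCorrelations:
    def test_identical_vectors_correlate_perfectly(self):
        import pandas as pd

        t1 = hr.ScoreTable("m1", pd.DataFrame(
            {"animal_id": list("ABCD"), "score": [1.0, 2, 3, 4]}))
        t2 = hr.ScoreTable("m2", pd.DataFrame(
            {"animal_id": list("ABCD"), "score": [1.0, 2, 3, 4]}))
        t3 = hr.ScoreTable("m3", pd.DataFrame(
            {"animal_id": list("ABCD"), "score": [-1.0, -2, -3, -4]}))
        reports = {(c.method_a, c.method_b): c
                   for c in hr.method_correlations([t1, t2, t3])}
        assert reports[("m1", "m2")].r == pytest.approx(1.0)
        assert reports[("m1", "m3")].r == pytest.approx(-1.0)
        assert reports[("m1", "m2")].n == 4

    def test_too_few_shared_animals_rejected(self):
        import pandas as pd

        t1 = hr.ScoreTable("m1", pd.DataFrame(
            {"animal_id": ["A", "B"], "score": [1.0, 2.0]}))
        t2 = hr.ScoreTable("m2", pd.DataFrame(
            {"animal_id": ["A", "B"], "score": [2.0, 1.0]}))
        with pytest.raises(hr.ValidationError):
            hr.method_correlations([t1, t2])

    def test_rank_agreement_on_clean_hierarchy(self):
        """With many observations and no upsets all three methods rank the
        herd in the latent order."""
        from scipy.stats import spearmanr

        lst, truth = hr.simulate_interactions(
            n_animals=8, n_events=1500, p_upset=0.0, seed=7)
        res = hr.analyze_interactions(lst)
        latent_rank = {a: i for i, a in enumerate(truth.latent_order)}
        for table in res.scores:
            s = table.series()
            ranks = [latent_rank[a] for a in s.index]
            rho = spearmanr(ranks, -s.to_numpy()).statistic
            assert rho > 0.95, table.method
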