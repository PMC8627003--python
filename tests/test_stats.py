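"""Permutation tests against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from _oracles import oracle_exhaustive_p
from rearlegacy import (
    AsvTable,
    bray_curtis,
    distlm_marginal,
    indicator_species,
    mann_whitney,
    pcoa,
    permanova,
    simper,
)


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(pts))


class TestPermanova:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (2, 4), (3, 4), (4, 4)])
    def test_exhaustive_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        d = random_distance_matrix(rng, n1 + n2)
        labels = ["a"] * n1 + ["b"] * n2
        res = permanova(d, labels, n_perm="exhaustive")
        assert res.table["p_value"].iloc[0] == pytest.approx(
            oracle_exhaustive_p(d, n1)
        )

    def test_pseudo_f_matches_skbio(self, tiny_table):
        dm = bray_curtis(tiny_table)
        ours = permanova(dm, tiny_table.grouping("group"), n_perm=99, seed=0)
        theirs = skbio_permanova(dm, tiny_table.metadata, column="group",
                                 permutations=99)
        assert ours.table["pseudo_F"].iloc[0] == pytest.approx(
            theirs["test statistic"]
        )

    def test_identical_groups_of_identical_samples(self):
        d = np.zeros((6, 6))
        res = permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=1)
        assert res.table["p_value"].iloc[0] == 1.0

    def test_strong_separation_detected(self, tiny_table):
        dm = bray_curtis(tiny_table)
        res = permanova(dm, tiny_table.grouping("group"), n_perm="exhaustive")
        # complete separation: the observed split is the most extreme of C(6,3)
        assert res.table["p_value"].iloc[0] == pytest.approx(2 / 20)

    def test_two_way_main_effects(self):
        rng = np.random.default_rng(5)
        # factor A shifts coordinates strongly, factor B not at all
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        pts = rng.normal(size=(16, 2)) + np.where(a == "a2", 6.0, 0.0)[:, None]
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = permanova(d, a, b, n_perm=199, seed=2)
        assert res.table.loc["factor1", "p_value"] < 0.05
        assert res.table.loc["factor2", "p_value"] > 0.1
        assert res.table.loc["factor1", "R2"] > res.table.loc["factor2", "R2"]

    def test_confounded_factors_rejected(self):
        d = random_distance_matrix(np.random.default_rng(0), 8)
        a = ["a"] * 4 + ["b"] * 4
        with pytest.raises(ValueError, match="confounded"):
            permanova(d, a, a, n_perm=99)

    def test_singleton_group_rejected(self):
        d = random_distance_matrix(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            permanova(d, ["a", "b", "b", "b", "b"], n_perm=99)


class TestSimper:
    def _table(self, rows, groups):
        df = pd.DataFrame(rows, columns=[f"A{j}" for j in range(len(rows[0]))])
        df.index = [f"s{i}" for i in range(len(rows))]
        return AsvTable(df), pd.Series(groups, index=df.index)

    def test_identical_groups_zero(self):
        t, g = self._table([[5, 5], [5, 5], [5, 5], [5, 5]], ["x", "x", "y", "y"])
        assert simper(t, g).overall == pytest.approx(0.0)

    def test_disjoint_single_asv_groups(self):
        t, g = self._table([[9, 0], [9, 0], [0, 9], [0, 9]], ["x", "x", "y", "y"])
        res = simper(t, g)
        assert res.overall == pytest.approx(100.0)
        assert res.contributions["contribution_pct"].sum() == pytest.approx(100.0)

    def test_contributions_match_pair_enumeration(self):
        t, g = self._table(
            [[6, 2, 1], [5, 3, 0], [1, 7, 4], [0, 6, 6]], ["x", "x", "y", "y"]
        )
        res = simper(t, g)
        x = t.counts.iloc[:2].to_numpy(float)
        y = t.counts.iloc[2:].to_numpy(float)
        expected = np.zeros(3)
        for xi in x:
            for yj in y:
                expected += np.abs(xi - yj) / (xi.sum() + yj.sum())
        expected = 100 * expected / 4
        got = res.contributions["contribution_pct"].reindex(["A0", "A1", "A2"])
        assert np.allclose(got.to_numpy(), expected)

    def test_overall_equals_mean_between_group_bray_curtis(self, tiny_table):
        res = simper(tiny_table, "group")
        dm = bray_curtis(tiny_table)
        g = tiny_table.grouping("group")
        xs = list(g.index[g == "x"])
        ys = list(g.index[g == "y"])
        mean_bc = np.mean([dm[str(i), str(j)] for i in xs for j in ys])
        assert res.overall == pytest.approx(100 * mean_bc)

    def test_singleton_group_rejected(self):
        t, g = self._table([[1, 2], [3, 4], [5, 6]], ["x", "x", "y"])
        with pytest.raises(ValueError):
            simper(t, g)


class TestIndicatorSpecies:
    def _table(self, rows, groups):
        df = pd.DataFrame(rows, columns=[f"A{j}" for j in range(len(rows[0]))])
        df.index = [f"s{i}" for i in range(len(rows))]
        return AsvTable(df), pd.Series(groups, index=df.index)

    def test_perfect_indicator(self):
        t, g = self._table(
            [[5, 1], [7, 1], [6, 1], [8, 1], [0, 1], [0, 1], [0, 1], [0, 1]],
            ["a", "a", "a", "a", "b", "b", "b", "b"],
        )
        res = indicator_species(t, g, n_perm=199, seed=0)
        assert res.loc["A0", "group"] == "a"
        assert res.loc["A0", "stat"] == pytest.approx(1.0)
        assert res.loc["A0", "p_value"] < 0.05

    def test_even_asv_scores_sqrt_half(self):
        t, g = self._table(
            [[4, 9], [4, 9], [4, 9], [4, 9]], ["a", "a", "b", "b"]
        )
        res = indicator_species(t, g, n_perm=49, seed=0)
        # equal means and full occurrence in both groups: sqrt(0.5 * 1)
        assert res.loc["A0", "stat"] == pytest.approx(math.sqrt(0.5))
        assert res.loc["A1", "stat"] == pytest.approx(math.sqrt(0.5))

    def test_constant_zero_asv_excluded(self):
        t, g = self._table([[5, 0], [6, 0], [1, 0], [2, 0]], ["a", "a", "b", "b"])
        res = indicator_species(t, g, n_perm=49, seed=0)
        assert "A1" not in res.index


class TestDistlm:
    def test_pcoa_axis_predictor_explains_its_eigenvalue_share(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3)) * np.array([3.0, 1.0, 0.5])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
        ords = pcoa(dm)
        x = pd.DataFrame({"axis1": ords.samples.iloc[:, 0].to_numpy()},
                         index=[str(i) for i in range(10)])
        res = distlm_marginal(dm, x, n_perm=99, seed=0)
        assert res.loc["axis1", "prop_explained"] == pytest.approx(
            float(ords.proportion_explained.iloc[0]), abs=1e-9
        )

    def test_duplicated_predictor_identical_results(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(rng, 8)
        x = rng.normal(size=8)
        preds = pd.DataFrame({"p1": x, "p2": x})
        res = distlm_marginal(d, preds, n_perm=99, seed=3)
        assert res.loc["p1"].equals(res.loc["p2"])

    def test_constant_predictor_rejected(self):
        d = random_distance_matrix(np.random.default_rng(0), 6)
        with pytest.raises(ValueError, match="constant"):
            distlm_marginal(d, pd.DataFrame({"c": np.ones(6)}), n_perm=9)


class TestMannWhitney:
    def test_complete_separation_and_identity(self):
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0
        x = [1.0, 2.0, 3.0]
        u2, p2 = mann_whitney(x, x)
        assert u2 == pytest.approx(len(x) ** 2 / 2)
        assert p2 == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        u, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_p_matches_enumeration(self):
        x = [1.2, 3.4, 5.6]
        y = [2.1, 4.3, 0.7, 6.5]
        u_obs, p_obs = mann_whitney(x, y)
        pooled = x + y
        n1 = len(x)
        n1n2 = len(x) * len(y)
        # enumerate every assignment of pooled values to the first sample
        us = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = sum(1 for a in xs for b in ys if a > b)
            us.append(u)
        us = np.array(us)
        crit = max(u_obs, n1n2 - u_obs)
        p_exact = min(1.0, 2 * np.mean(us >= crit))
        assert p_obs == pytest.approx(p_exact)
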