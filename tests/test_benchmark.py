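import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spacomm as sp
from spacomm.benchmark import (
    coexpression_percent,
    evaluate_composition,
    fisher_pathway_enrichment,
    simulate_spots,
    spatial_proximity_test,
)
from spacomm.communication import build_knn_graph, count_lr_pairs


def _corner_cells():
    coords = pd.DataFrame({
        "unit": ["a", "b", "c", "d"],
        "x": [0.0, 1.0, 0.0, 1.0],
        "y": [0.0, 0.0, 1.0, 1.0],
    })
    expr = sp.ExpressionMatrix(["G1", "G2"], ["a", "b", "c", "d"],
                               np.arange(8, dtype=float).reshape(2, 4) + 1)
    labels = {"a": "T1", "b": "T1", "c": "T2", "d": "T2"}
    return expr, sp.SpatialCoordinates(coords), labels


class TestSimulateSpots:
    def test_one_spot_when_bin_covers_all(self):
        expr, coords, labels = _corner_cells()
        spots = simulate_spots(expr, coords, labels, bin_size=2.0)
        assert spots.expression.n_units == 1
        np.testing.assert_allclose(
            spots.expression.counts[:, 0], expr.counts.sum(axis=1))
        np.testing.assert_allclose(spots.truth.iloc[0].to_numpy(), [0.5, 0.5])

    def test_singleton_spots_at_unit_bins(self):
        expr, coords, labels = _corner_cells()
        spots = simulate_spots(expr, coords, labels, bin_size=1.0)
        assert spots.expression.n_units == 4
        for s, members in spots.members.items():
            assert len(members) == 1

    def test_count_conservation_random_fixture(self, small_spatial):
        st, coords, labels = small_spatial
        spots = simulate_spots(st, coords, labels, bin_size=0.23)
        assert spots.expression.counts.sum() == st.counts.sum()
        assert sum(len(m) for m in spots.members.values()) == st.n_units
        # truth proportions sum to one per spot
        np.testing.assert_allclose(spots.truth.sum(axis=1), 1.0)

    def test_invalid_bin_size(self):
        expr, coords, labels = _corner_cells()
        with pytest.raises(ValueError, match="bin_size"):
            simulate_spots(expr, coords, labels, bin_size=0.0)


class TestEvaluateComposition:
    def test_perfect_prediction(self):
        truth = pd.DataFrame([[0.5, 0.5], [0.9, 0.1]], index=["s1", "s2"],
                             columns=["A", "B"])
        res = evaluate_composition(truth.copy(), truth)
        assert res["mean_pearson"] == pytest.approx(1.0)
        assert res["mean_rmse"] == 0.0

    def test_uniform_vs_one_hot_closed_form(self):
        truth = pd.DataFrame([[1.0, 0.0, 0.0]], index=["s"], columns=list("ABC"))
        pred = pd.DataFrame([[1 / 3] * 3], index=["s"], columns=list("ABC"))
        res = evaluate_composition(pred, truth)
        assert res["mean_rmse"] == pytest.approx(np.sqrt(2.0 / 9.0))

    def test_matches_second_implementation(self, rng):
        k, s = 4, 30
        truth = pd.DataFrame(rng.dirichlet(np.ones(k), size=s),
                             index=[f"s{i}" for i in range(s)],
                             columns=[f"T{j}" for j in range(k)])
        pred = truth + rng.normal(0, 0.05, size=(s, k))
        res = evaluate_composition(pred, truth)
        exp_r = np.mean([stats.pearsonr(pred.iloc[i], truth.iloc[i])[0]
                         for i in range(s)])
        exp_rmse = np.mean(np.sqrt(((pred - truth) ** 2).mean(axis=1)))
        assert res["mean_pearson"] == pytest.approx(exp_r)
        assert res["mean_rmse"] == pytest.approx(exp_rmse)

    def test_constant_truth_spot_skipped(self):
        truth = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]], index=["s1", "s2"],
                             columns=["A", "B"])
        pred = pd.DataFrame([[0.7, 0.3], [0.9, 0.1]], index=["s1", "s2"],
                            columns=["A", "B"])
        with pytest.warns(UserWarning, match="constant"):
            res = evaluate_composition(pred, truth)
        assert np.isnan(res["pearson"]["s1"])
        assert not np.isnan(res["pearson"]["s2"])


class TestSpatialProximity:
    def test_extremely_proximal_exact_tail(self, rng):
        # 5 sender-receiver distances all strictly below 20 background ones:
        # exact one-sided P = 1 / C(25, 5)
        n1, n2 = 5, 20
        x = np.sort(rng.uniform(0.0, 0.1, n1))
        y = np.sort(rng.uniform(1.0, 2.0, n2))
        res = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        assert res.pvalue == pytest.approx(1.0 / math.comb(n1 + n2, n1))

    def test_planted_layout_significant(self, rng):
        # senders and receivers adjacent; decoy cells far away
        n = 40
        coords = np.vstack([
            rng.uniform([0, 0], [0.1, 0.1], size=(10, 2)),       # A senders
            rng.uniform([0.1, 0], [0.2, 0.1], size=(10, 2)),     # B receivers
            rng.uniform([5, 5], [6, 6], size=(20, 2)),           # others
        ])
        types = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 20, dtype=object)
        counts = np.zeros((2, n))
        counts[0, :10] = 4.0
        counts[1, 10:20] = 4.0
        expr = sp.ExpressionMatrix(["L", "R"], [f"c{i}" for i in range(n)],
                                   counts)
        p, flags = spatial_proximity_test(coords, types, expr, "L", "R",
                                          "A", "B", rng=rng)
        assert p < 0.01
        assert not flags["no_pairs"]

    def test_null_layout_roughly_uniform(self, rng):
        n = 60
        ps = []
        for _ in range(40):
            coords = rng.uniform(0, 1, size=(n, 2))
            types = np.array(["A", "B"], dtype=object)[rng.integers(0, 2, n)]
            counts = rng.poisson(1.0, size=(2, n)).astype(float)
            expr = sp.ExpressionMatrix(["L", "R"],
                                       [f"c{i}" for i in range(n)], counts)
            p, _ = spatial_proximity_test(coords, types, expr, "L", "R",
                                          "A", "B", rng=rng)
            ps.append(p)
        # no gross anti-conservatism under the null
        assert np.mean(np.array(ps) < 0.05) <= 0.15

    def test_no_expressing_pairs_flagged(self, rng):
        coords = rng.uniform(0, 1, size=(10, 2))
        types = np.array(["A", "B"] * 5, dtype=object)
        expr = sp.ExpressionMatrix(["L", "R"], [f"c{i}" for i in range(10)],
                                   np.zeros((2, 10)))
        p, flags = spatial_proximity_test(coords, types, expr, "L", "R",
                                          "A", "B", rng=rng)
        assert p == 1.0
        assert flags["no_pairs"]


class TestCoexpressionPercent:
    def _graph(self, rng, n=30):
        coords = rng.uniform(0, 1, size=(n, 2))
        types = np.array(["A", "B"], dtype=object)[rng.integers(0, 2, n)]
        return build_knn_graph(coords, types, cells=[f"c{i}" for i in range(n)],
                               K=4)

    def test_all_edges_coexpress(self, rng):
        g = self._graph(rng)
        expr = sp.ExpressionMatrix(["L", "R"], g.cells,
                                   np.ones((2, g.n_cells)))
        assert coexpression_percent(g, expr, "A", "B", "L", "R") == 100.0

    def test_none_coexpress(self, rng):
        g = self._graph(rng)
        expr = sp.ExpressionMatrix(["L", "R"], g.cells,
                                   np.zeros((2, g.n_cells)))
        assert coexpression_percent(g, expr, "A", "B", "L", "R") == 0.0

    def test_matches_brute_force_ratio(self, rng):
        g = self._graph(rng)
        counts = rng.poisson(0.7, size=(2, g.n_cells)).astype(float)
        expr = sp.ExpressionMatrix(["L", "R"], g.cells, counts)
        pct = coexpression_percent(g, expr, "A", "B", "L", "R")
        c0 = count_lr_pairs(g, expr, "A", "B", "L", "R")
        n_ab = int(g.edges_between("A", "B").sum())
        assert pct == pytest.approx(100.0 * c0 / n_ab)


def _fisher_oracle(a, b, c, d):
    """Exact upper-tail hypergeometric by integer enumeration."""
    n, K, N = a + b + c + d, a + b, a + c
    denom = math.comb(n, N)
    total = 0
    for aa in range(a, min(K, N) + 1):
        if N - aa <= n - K:
            total += math.comb(K, aa) * math.comb(n - K, N - aa)
    return total / denom


class TestFisherEnrichment:
    def test_extreme_table_closed_form(self):
        universe = [f"G{i}" for i in range(20)]
        targets = universe[:5]
        table = fisher_pathway_enrichment(targets, {"P": set(targets)},
                                          universe)
        assert table.loc[0, "a"] == 5
        assert table.loc[0, "p"] == pytest.approx(1.0 / math.comb(20, 5))

    def test_disjoint_targets_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        table = fisher_pathway_enrichment(universe[10:12],
                                          {"P": set(universe[:5])}, universe)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_target_set_all_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        table = fisher_pathway_enrichment([], {"P": set(universe[:3])},
                                          universe)
        assert (table["p"] == 1.0).all()

    def test_matches_enumeration_oracle(self, rng):
        universe = [f"G{i}" for i in range(40)]
        for _ in range(100):
            targets = rng.choice(universe, size=rng.integers(1, 15),
                                 replace=False)
            pw = set(rng.choice(universe, size=rng.integers(1, 20),
                                replace=False))
            table = fisher_pathway_enrichment(targets, {"P": pw}, universe)
            a, b, c, d = table.loc[0, ["a", "b", "c", "d"]]
            assert table.loc[0, "p"] == pytest.approx(
                _fisher_oracle(a, b, c, d), abs=1e-12)

    def test_gene_order_invariance_and_monotone_in_a(self):
        universe = [f"G{i}" for i in range(30)]
        pw = set(universe[:10])
        t1 = fisher_pathway_enrichment(universe[:8], {"P": pw}, universe)
        t2 = fisher_pathway_enrichment(universe[:8][::-1], {"P": pw},
                                       list(reversed(universe)))
        assert t1.loc[0, "p"] == pytest.approx(t2.loc[0, "p"])
        # P decreases as overlap a grows at fixed margins
        ps = []
        for a in range(0, 9):
            targets = universe[:a] + universe[10:10 + (8 - a)]
            ps.append(fisher_pathway_enrichment(targets, {"P": pw},
                                                universe).loc[0, "p"])
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))
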