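"""Centrality measures, ranking, rank correlation and consensus."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio import centrality as ct

import oracles


class TestMeasureExamples:
    def test_cycle_is_vertex_transitive(self):
        g = nx.cycle_graph(5)
        table = ct.compute_centralities(g)
        for m in table.measures:
            col = table.scores[m]
            assert np.allclose(col, col.iloc[0]), m

    def test_star_center(self, star_graph):
        table = ct.compute_centralities(star_graph)
        s = table.scores
        assert s.loc["hub", "degree"] == 3
        assert s.loc["hub", "betweenness"] == 3  # the C(3,2) leaf pairs
        assert s.loc["hub", "stress"] == 3
        assert s.loc["hub", "centroid"] == 2
        assert all(s.loc[leaf, "centroid"] == -2 for leaf in ("x", "y", "z"))

    def test_path_vulnerability(self, path_graph):
        table = ct.compute_centralities(path_graph, ["vulnerability"])
        assert table.scores.loc["b", "vulnerability"] == pytest.approx(1.0)
        assert table.scores.loc["a", "vulnerability"] == pytest.approx(-0.2)

    def test_disconnected_errors(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            ct.compute_centralities(g)

    def test_unknown_measure_errors(self, path_graph):
        with pytest.raises(ValueError, match="unknown"):
            ct.compute_centralities(path_graph, ["degree", "bogus"])


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(2024)
    return [oracles.random_connected_graph(rng) for _ in range(60)]


class TestOracleEquivalence:
    """Implementation vs brute force on seeded random connected graphs."""

    def test_path_measures_match_enumeration(self, graphs):
        for g in graphs:
            nodes = sorted(g.nodes())
            table = ct.compute_centralities(
                g, ["betweenness", "stress", "closeness", "radiality", "centroid"]
            )
            bet, stress = oracles.brute_betweenness_stress(g, nodes)
            dist = oracles.distance_matrix(g, nodes)
            for i, v in enumerate(nodes):
                assert table.scores.loc[v, "betweenness"] == pytest.approx(bet[v])
                assert table.scores.loc[v, "stress"] == pytest.approx(stress[v])
                assert table.scores.loc[v, "closeness"] == pytest.approx(
                    oracles.brute_closeness(dist, i)
                )
                assert table.scores.loc[v, "radiality"] == pytest.approx(
                    oracles.brute_radiality(dist, i)
                )
                assert table.scores.loc[v, "centroid"] == oracles.brute_centroid(dist, i)

    def test_eigenvector_satisfies_eigen_equation(self, graphs):
        for g in graphs[:30]:
            nodes = sorted(g.nodes())
            table = ct.compute_centralities(g, ["eigenvector"])
            vec = table.scores["eigenvector"].to_numpy()
            adj = nx.to_numpy_array(g, nodelist=nodes)
            lam = vec @ adj @ vec  # Rayleigh quotient of the unit vector
            assert np.linalg.norm(adj @ vec - lam * vec) <= 1e-8

    def test_pagerank_matches_power_iteration_and_sums_to_one(self, graphs):
        for g in graphs[:20]:
            nodes = sorted(g.nodes())
            table = ct.compute_centralities(g, ["pagerank"])
            got = table.scores["pagerank"].to_numpy()
            want = oracles.brute_pagerank(g, nodes)
            assert np.allclose(got, want, atol=1e-8)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)

    def test_current_flow_measures_match_pair_solves(self, graphs):
        for g in graphs[:20]:
            nodes = sorted(g.nodes())
            table = ct.compute_centralities(
                g, ["current_flow_betweenness", "current_flow_closeness"]
            )
            cfb = oracles.brute_current_flow_betweenness(g, nodes)
            cfc = oracles.brute_current_flow_closeness(g, nodes)
            for v in nodes:
                assert table.scores.loc[v, "current_flow_betweenness"] == pytest.approx(
                    cfb[v], abs=1e-8
                )
                assert table.scores.loc[v, "current_flow_closeness"] == pytest.approx(
                    cfc[v], abs=1e-8
                )

    def test_vulnerability_matches_removal_oracle(self, graphs):
        for g in graphs[:15]:
            nodes = sorted(g.nodes())
            table = ct.compute_centralities(g, ["vulnerability"])
            for v in nodes:
                assert table.scores.loc[v, "vulnerability"] == pytest.approx(
                    oracles.brute_vulnerability(g, v)
                )

    def test_adding_an_edge_never_decreases_degree_or_eigenvector(self, graphs):
        for g in graphs[:15]:
            nodes = sorted(g.nodes())
            missing = [
                (u, v)
                for i, u in enumerate(nodes)
                for v in nodes[i + 1 :]
                if not g.has_edge(u, v)
            ]
            if not missing:
                continue
            u, v = missing[0]
            before = ct.compute_centralities(g, ["degree", "eigenvector"]).scores
            h = g.copy()
            h.add_edge(u, v)
            after = ct.compute_centralities(h, ["degree", "eigenvector"]).scores
            for w in (u, v):
                assert after.loc[w, "degree"] >= before.loc[w, "degree"]
                assert after.loc[w, "eigenvector"] >= before.loc[w, "eigenvector"] - 1e-10


class TestRankTable:
    def test_tie_handling(self):
        scores = pd.DataFrame({"m": [5.0, 5.0, 1.0]}, index=["g1", "g2", "g3"])
        frac, ordi = ct.rank_table(scores)
        assert list(frac["m"]) == [1.5, 1.5, 3.0]
        assert list(ordi["m"]) == [1.0, 2.0, 3.0]

    def test_no_ties_fractional_equals_ordinal(self):
        scores = pd.DataFrame({"m": [9.0, 7.0, 5.0, 3.0]}, index=list("abcd"))
        frac, ordi = ct.rank_table(scores)
        assert (frac == ordi).all().all()
        assert list(ordi["m"]) == [1.0, 2.0, 3.0, 4.0]

    def test_full_tie(self):
        scores = pd.DataFrame({"m": [2.0] * 4}, index=list("abcd"))
        frac, _ = ct.rank_table(scores)
        assert list(frac["m"]) == [2.5] * 4

    def test_fractional_ranks_sum(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {"m": rng.integers(0, 4, size=10).astype(float)},
            index=[f"g{i}" for i in range(10)],
        )
        frac, ordi = ct.rank_table(scores)
        assert frac["m"].sum() == 10 * 11 / 2
        assert sorted(ordi["m"]) == list(range(1, 11))

    def test_nan_errors(self):
        scores = pd.DataFrame({"m": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ct.rank_table(scores)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        rev = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert ct.spearman_rho(x, x) == pytest.approx(1.0)
        assert ct.spearman_rho(x, rev) == pytest.approx(-1.0)

    def test_reversal_matches_closed_form(self):
        # n=3 reversal: sum d^2 = 8 -> 1 - 48/24 = -1
        a = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        b = {"g1": 3.0, "g2": 2.0, "g3": 1.0}
        d2 = sum((a[g] - b[g]) ** 2 for g in a)
        closed = 1 - 6 * d2 / (3 * (9 - 1))
        assert ct.spearman_rho(a, b) == pytest.approx(closed)

    def test_ties_equal_product_moment(self):
        a = {"g1": 1.5, "g2": 1.5, "g3": 3.0}
        b = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        want = np.corrcoef([1.5, 1.5, 3.0], [1.0, 2.0, 3.0])[0, 1]
        assert ct.spearman_rho(a, b) == pytest.approx(want)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            ct.spearman_rho({"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 2.0})

    def test_mismatched_genes_error(self):
        with pytest.raises(ValueError):
            ct.spearman_rho({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0})


class TestRadialityClosenessCollapse:
    def test_identical_ordinal_rankings_on_sampled_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            g = oracles.random_connected_graph(rng, n_min=4, n_max=9)
            table = ct.compute_centralities(g, ["closeness", "radiality"])
            assert (
                table.ordinal_ranks["closeness"] == table.ordinal_ranks["radiality"]
            ).all()
            if table.scores["closeness"].nunique() > 1:
                rho = ct.rank_correlation_matrix(table.fractional_ranks)
                assert rho.loc["closeness", "radiality"] == pytest.approx(1.0)


class TestPruneRedundant:
    def _rho(self, names, pairs):
        frame = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, v in pairs:
            frame.loc[a, b] = frame.loc[b, a] = v
        return frame

    def test_perfect_pair_collapses_keeping_first(self):
        names = ["degree", "closeness", "radiality"]
        rho = self._rho(names, [("closeness", "radiality", 1.0), ("degree", "closeness", 0.9)])
        assert ct.prune_redundant_measures(rho) == ["degree", "closeness"]

    def test_no_pair_at_threshold_keeps_all(self):
        names = ["a", "b", "c"]
        rho = self._rho(names, [("a", "b", 0.99)])
        assert ct.prune_redundant_measures(rho) == names

    def test_transitive_group_keeps_one(self):
        names = ["a", "b", "c", "d"]
        rho = self._rho(names, [("a", "b", 1.0), ("b", "c", 1.0)])
        assert ct.prune_redundant_measures(rho) == ["a", "d"]

    def test_eleven_collapse_to_ten_on_real_table(self, star_graph):
        g = nx.barbell_graph(4, 2)
        table = ct.compute_centralities(g)
        rho = ct.rank_correlation_matrix(table.fractional_ranks)
        kept = ct.prune_redundant_measures(rho)
        assert "radiality" not in kept
        assert "closeness" in kept


class TestConsensus:
    def test_single_measure_identity(self):
        ordi = pd.DataFrame({"m": [2.0, 1.0, 3.0]}, index=["a", "b", "c"])
        cons = ct.consensus_ranking(ordi)
        assert cons.order == ["b", "a", "c"]

    def test_hand_summed_example_with_tie(self):
        ordi = pd.DataFrame(
            {"m1": [1.0, 2.0, 3.0], "m2": [2.0, 1.0, 3.0]}, index=["g1", "g2", "g3"]
        )
        cons = ct.consensus_ranking(ordi)
        assert list(cons.rank_sum) == [3.0, 3.0, 6.0]
        assert cons.order == ["g1", "g2", "g3"]  # tie broken by gene id

    def test_dominant_gene_ranks_first(self):
        ordi = pd.DataFrame(
            {"m1": [1.0, 2.0, 3.0], "m2": [1.0, 3.0, 2.0]}, index=["top", "u", "v"]
        )
        assert ct.consensus_ranking(ordi).order[0] == "top"

    def test_invariant_under_measure_permutation(self):
        rng = np.random.default_rng(3)
        ordi = pd.DataFrame(
            rng.permuted(np.tile(np.arange(1.0, 9.0), (4, 1)).T, axis=0),
            index=[f"g{i}" for i in range(8)],
            columns=list("wxyz"),
        )
        a = ct.consensus_ranking(ordi)
        b = ct.consensus_ranking(ordi[["z", "x", "w", "y"]])
        assert a.order == b.order
        assert (a.rank_sum == b.rank_sum).all()


class TestSelectTopFraction:
    def _consensus(self, n):
        ordi = pd.DataFrame(
            {"m": np.arange(1.0, n + 1)}, index=[f"g{i:03d}" for i in range(n)]
        )
        return ct.consensus_ranking(ordi)

    def test_basic_counts(self):
        cons = self._consensus(100)
        assert len(ct.select_top_fraction(cons, 0.05)) == 5
        assert len(ct.select_top_fraction(cons, 1.0)) == 100

    def test_round_vs_floor(self):
        cons = self._consensus(227)
        assert len(ct.select_top_fraction(cons, 0.05, policy="round")) == 11
        assert len(ct.select_top_fraction(cons, 0.05, policy="floor")) == 11
        cons2 = self._consensus(30)
        assert len(ct.select_top_fraction(cons2, 0.05, policy="round")) == 2
        assert len(ct.select_top_fraction(cons2, 0.05, policy="floor")) == 1

    def test_zero_selection_errors(self):
        cons = self._consensus(10)
        with pytest.raises(ValueError):
            ct.select_top_fraction(cons, 0.04, policy="floor")

    def test_distinct_policy_extends_over_ties(self):
        scores = pd.Series([5.0, 3.0, 3.0, 1.0], index=["a", "b", "c", "d"])
        ranks = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        top = ct.select_top_fraction(ranks, 0.5, policy="distinct", scores=scores)
        assert top == ["a", "b", "c"]
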