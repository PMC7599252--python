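import itertools

import networkx as nx
import numpy as np
import pytest

import netbiomark as nb
from netbiomark.proximity import DistanceCache

from conftest import graph_from_edges, path_network


class TestClosestDistance:
    def test_path_graph_nearest_member_wins(self):
        net = path_network("abcde")
        assert nb.closest_distance(net, {"a"}, {"d", "e"}) == 3.0

    def test_subset_gives_zero(self):
        net = path_network("abc")
        assert nb.closest_distance(net, {"a", "b"}, {"a", "b", "c"}) == 0.0

    def test_average_over_targets(self):
        net = path_network("abc")
        assert nb.closest_distance(net, {"a", "c"}, {"b"}) == 1.0

    def test_cache_agrees_with_bfs(self):
        net = path_network("abcde")
        cache = DistanceCache(net)
        for T, S in [({"a"}, {"d", "e"}), ({"a", "c"}, {"b"}), ({"b"}, {"e"})]:
            assert nb.closest_distance(net, T, S) == \
                nb.closest_distance(net, T, S, cache=cache)

    def test_empty_sets_error(self):
        net = path_network("abc")
        with pytest.raises(ValueError):
            nb.closest_distance(net, set(), {"a"})
        with pytest.raises(ValueError):
            nb.closest_distance(net, {"zz"}, {"a"})

    def test_monotone_as_pathway_grows(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            net = nb.InteractionNetwork(nx.relabel_nodes(g, str))
            nodes = sorted(net.nodes)
            T = set(rng.choice(nodes, 3, replace=False))
            S = set(rng.choice(nodes, 4, replace=False))
            S_big = S | set(rng.choice(nodes, 4, replace=False))
            assert nb.closest_distance(net, T, S_big) <= \
                nb.closest_distance(net, T, S)

    def test_asymmetry_intended(self):
        net = path_network("abcd")
        assert nb.closest_distance(net, {"a"}, {"c", "d"}) == 2.0
        assert nb.closest_distance(net, {"c", "d"}, {"a"}) == 2.5


class TestDegreeBins:
    def degree_graph(self):
        # degrees: a=1, b=1, f=1, d=2, e=2, c=3
        return graph_from_edges(
            [("c", "a"), ("c", "b"), ("c", "d"), ("d", "e"), ("e", "f")])

    def test_greedy_merge(self):
        binning = nb.build_degree_bins(self.degree_graph(), min_bin_size=3)
        assert len(binning.bins) == 2
        assert set(binning.bins[0]) == {"a", "b", "f"}
        assert set(binning.bins[1]) == {"c", "d", "e"}

    def test_min_size_one_all_distinct_degrees(self):
        net = path_network("abc")  # degrees 1,2,1 -> two distinct values
        binning = nb.build_degree_bins(net, min_bin_size=1)
        assert len(binning.bins) == 2

    def test_single_bin_when_min_is_n(self):
        net = self.degree_graph()
        binning = nb.build_degree_bins(net, min_bin_size=net.n_nodes)
        assert len(binning.bins) == 1

    def test_oversized_min_errors(self):
        with pytest.raises(ValueError):
            nb.build_degree_bins(self.degree_graph(), min_bin_size=99)

    def test_every_node_assigned_once(self):
        net = self.degree_graph()
        binning = nb.build_degree_bins(net, min_bin_size=2)
        assert set(binning.assignment) == net.nodes
        assert sum(len(b) for b in binning.bins) == net.n_nodes


class TestSampleDegreeMatched:
    def test_cardinality_and_bin_membership(self):
        net = graph_from_edges(
            [("c", "a"), ("c", "b"), ("c", "d"), ("d", "e"), ("e", "f")])
        binning = nb.build_degree_bins(net, min_bin_size=3)
        genes = {"a", "d", "c"}
        for seed in range(10):
            out = nb.sample_degree_matched(net, genes, binning, seed=seed)
            assert len(out) == len(genes)
            drawn_bins = sorted(binning.assignment[g] for g in out)
            wanted_bins = sorted(binning.assignment[g] for g in genes)
            assert drawn_bins == wanted_bins

    def test_singleton_bins_force_identity(self):
        net = graph_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("c", "e")])
        # degrees: a1,b2,c3,d1,e1 -> with min_bin_size=1: bins {a,d,e},{b},{c}
        binning = nb.build_degree_bins(net, min_bin_size=1)
        out = nb.sample_degree_matched(net, {"b", "c"}, binning, seed=0)
        assert out == {"b", "c"}

    def test_deterministic_under_seed(self):
        net = path_network("abcdefgh")
        binning = nb.build_degree_bins(net, min_bin_size=2)
        a = nb.sample_degree_matched(net, {"a", "c", "e"}, binning, seed=42)
        b = nb.sample_degree_matched(net, {"a", "c", "e"}, binning, seed=42)
        assert a == b


class TestProximityZscore:
    def test_complete_graph_not_proximal(self):
        # every node is adjacent to every other: the observed distance
        # carries no signal against the randomized null
        net = graph_from_edges(itertools.combinations("abcde", 2))
        rec = nb.proximity_zscore(net, {"a", "b"}, {"d", "e"}, n_iter=50, seed=1)
        assert rec.d_c == 1.0
        assert rec.z >= 0.0 and not rec.proximal

    def test_singleton_bins_degenerate_sigma_zero(self):
        # T and S fall in single-node degree bins, so every null draw is
        # identical: sigma = 0 -> z defined as 0, not proximal
        net = graph_from_edges(
            [("a", "hub"), ("b", "hub"), ("c", "hub"), ("c", "d")])
        rec = nb.proximity_zscore(net, {"hub"}, {"c"}, n_iter=20,
                                  min_bin_size=1, seed=0)
        assert rec.sigma_null == 0.0
        assert rec.z == 0.0 and not rec.proximal

    def test_enumeration_oracle_small_graph(self):
        """Sampled z agrees with the exact degree-matched null computed
        by brute-force enumeration on an 8-node graph."""
        net = graph_from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
             ("e", "f"), ("f", "g"), ("g", "h"), ("b", "g")])
        binning = nb.build_degree_bins(net, min_bin_size=3)
        T, S = {"a"}, {"e"}
        # exact null: enumerate every degree-matched (t', s') pair
        t_bin = binning.bins[binning.assignment["a"]]
        s_bin = binning.bins[binning.assignment["e"]]
        dists = [nb.closest_distance(net, {t}, {s})
                 for t in t_bin for s in s_bin]
        mu, sd = np.mean(dists), np.std(dists)
        d_obs = nb.closest_distance(net, T, S)
        z_exact = (d_obs - mu) / sd
        rec = nb.proximity_zscore(net, T, S, n_iter=1000, min_bin_size=3, seed=7)
        mc_se = 3 * 1.0 / np.sqrt(1000)  # 3 MC standard errors (sd approx 1)
        assert rec.z == pytest.approx(z_exact, abs=3 * mc_se + 0.15)

    def test_deterministic_under_seed(self):
        net = path_network("abcdefgh")
        r1 = nb.proximity_zscore(net, {"a"}, {"f"}, n_iter=200, seed=5)
        r2 = nb.proximity_zscore(net, {"a"}, {"f"}, n_iter=200, seed=5)
        assert (r1.d_c, r1.mu_null, r1.sigma_null, r1.z) == \
            (r2.d_c, r2.mu_null, r2.sigma_null, r2.z)


class TestThresholdAndSelection:
    def test_alpha_quantiles(self):
        assert nb.proximal_z_threshold(0.10) == pytest.approx(-1.2816, abs=5e-5)
        assert nb.proximal_z_threshold(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_records_sorted_by_z(self, scenario):
        records = nb.select_proximal_pathways(
            scenario.network, scenario.drug_targets["drugX"],
            scenario.pathways, n_iter=100, seed=2)
        zs = [r.z for r in records]
        assert zs == sorted(zs)
        assert len(records) == len(scenario.pathways)


class TestCentralityBaselines:
    def star(self):
        return graph_from_edges([("hub", f"l{i}") for i in range(5)])

    def test_star_degree_scores(self):
        net = self.star()
        coll = nb.GeneSetCollection({"H": {"hub"}, "L": {"l0"}})
        scores = nb.pathway_centrality(net, coll, "degree")
        assert scores["H"] == 5 and scores["L"] == 1

    def test_identical_sets_identical_scores(self):
        net = self.star()
        coll = nb.GeneSetCollection({"A": {"hub", "l0"}, "B": {"hub", "l0"}})
        for m in ("degree", "betweenness", "closeness"):
            s = nb.pathway_centrality(net, coll, m)
            assert s["A"] == s["B"]

    def test_closeness_path_center(self):
        net = path_network("abc")
        coll = nb.GeneSetCollection({"C": {"b"}})
        assert nb.pathway_centrality(net, coll, "closeness")["C"] == \
            pytest.approx(1.0)

    def test_unknown_measure_errors(self):
        with pytest.raises(ValueError):
            nb.pathway_centrality(self.star(), nb.GeneSetCollection({"H": {"hub"}}),
                                  "eigenvector")

    def test_select_central_top_k(self):
        net = self.star()
        coll = nb.GeneSetCollection({"H": {"hub"}, "L": {"l0"}, "M": {"l1"}})
        assert nb.select_central_pathways(net, coll, "degree", 1) == ["H"]
        assert set(nb.select_central_pathways(net, coll, "degree", 3)) == \
            {"H", "L", "M"}
        # L and M tie at degree 1; lexicographically smaller kept at k=2
        assert nb.select_central_pathways(net, coll, "degree", 2) == ["H", "L"]
        with pytest.raises(ValueError):
            nb.select_central_pathways(net, coll, "degree", 0)


class TestNeighborGeneSet:
    net = path_network("abcd")

    def test_depth_one(self):
        assert nb.neighbor_gene_set(self.net, {"a"}, 1) == {"a", "b"}

    def test_depth_zero_is_targets(self):
        assert nb.neighbor_gene_set(self.net, {"a", "c"}, 0) == {"a", "c"}

    def test_depth_at_diameter_covers_graph(self):
        assert nb.neighbor_gene_set(self.net, {"a"}, 3) == self.net.nodes

    def test_depth_cap(self):
        with pytest.raises(ValueError):
            nb.neighbor_gene_set(self.net, {"a"}, 4)
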