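"""Network filtering and the four hub centralities vs brute oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from teashuttle import network, reference, simulate
from teashuttle.errors import EdgeListParseError

from conftest import random_graph


def edges_df(pairs, score=900):
    return pd.DataFrame([{"protein1": a, "protein2": b,
                          "combined_score": score} for a, b in pairs])


def brute_mcc(g: nx.Graph) -> dict:
    """All-subsets maximal-clique enumeration (graphs up to ~12 nodes)."""
    from math import factorial

    nodes = list(g)
    cliques = [frozenset(sub)
               for r in range(1, len(nodes) + 1)
               for sub in itertools.combinations(nodes, r)
               if all(g.has_edge(a, b)
                      for a, b in itertools.combinations(sub, 2))]
    maximal = [c for c in cliques
               if not any(c < d for d in cliques)]
    scores = {v: 0.0 for v in nodes}
    for c in maximal:
        for v in c:
            scores[v] += factorial(len(c) - 1)
    return scores


def brute_mnc(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        sub = g.subgraph(g[v])
        out[v] = max((len(c) for c in nx.connected_components(sub)),
                     default=0)
    return out


class TestBuildNetwork:
    def test_triangle_pruned_k4_kept(self):
        tri = network.build_network(
            edges_df([("a", "b"), ("b", "c"), ("a", "c")]))
        assert tri.number_of_nodes() == 0
        k4 = network.build_network(
            edges_df(itertools.combinations("abcd", 2)))
        assert set(k4) == set("abcd") and k4.number_of_edges() == 6

    def test_score_cutoff_and_dedup(self):
        df = pd.DataFrame([
            {"protein1": "a", "protein2": "b", "combined_score": 699},
            {"protein1": "a", "protein2": "a", "combined_score": 900},
            {"protein1": "a", "protein2": "b", "combined_score": 900},
            {"protein1": "b", "protein2": "a", "combined_score": 950},
        ])
        g = network.build_network(df, min_degree_keep=0)
        assert g.number_of_edges() == 1

    def test_matches_naive_filter_oracle(self):
        rng = np.random.default_rng(2)
        names = [f"n{i}" for i in range(12)]
        rows = [{"protein1": a, "protein2": b,
                 "combined_score": float(rng.integers(0, 1001))}
                for a, b in itertools.combinations(names, 2)
                if rng.random() < 0.5]
        df = pd.DataFrame(rows)
        g = network.build_network(df)
        strong = nx.Graph([(r["protein1"], r["protein2"])
                           for r in rows if r["combined_score"] >= 700])
        strong.remove_nodes_from(
            [v for v in list(strong) if strong.degree(v) <= 2])
        assert set(g) == set(strong)
        assert set(map(frozenset, g.edges)) == \
            set(map(frozenset, strong.edges))

    def test_malformed_score_raises_with_line(self):
        df = pd.DataFrame([{"protein1": "a", "protein2": "b",
                            "combined_score": 1200}])
        with pytest.raises(EdgeListParseError, match="line 1"):
            network.build_network(df)


class TestCentralities:
    def test_hand_examples(self):
        tri = nx.complete_graph(3)
        assert network.mcc(tri) == {0: 2.0, 1: 2.0, 2: 2.0}
        k4 = nx.complete_graph(4)
        assert set(network.mcc(k4).values()) == {6.0}
        path = nx.path_graph(3)          # a-b-c
        assert network.mcc(path) == {0: 1.0, 1: 2.0, 2: 1.0}
        clo = network.closeness_centrality(path)
        assert clo[1] == pytest.approx(2.0)
        assert clo[0] == pytest.approx(1.5)
        assert set(network.closeness_centrality(k4).values()) == {3.0}
        star = nx.star_graph(4)
        assert network.mnc(star)[0] == 1.0
        assert network.mnc(tri)[0] == 2.0
        assert network.mnc(nx.empty_graph(3))[0] == 0.0
        assert network.degree_centrality(star)[0] == 4.0

    def test_random_graphs_match_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            g = random_graph(rng)
            assert network.mcc(g) == pytest.approx(brute_mcc(g))
            assert network.mnc(g) == pytest.approx(brute_mnc(g))
            assert network.closeness_centrality(g) == pytest.approx(
                nx.harmonic_centrality(g))
            adj = nx.to_numpy_array(g, nodelist=sorted(g))
            degs = dict(zip(sorted(g), adj.sum(axis=1)))
            assert network.degree_centrality(g) == pytest.approx(degs)

    def test_two_components_no_cross_contribution(self):
        g = nx.union(nx.complete_graph(3),
                     nx.relabel_nodes(nx.complete_graph(3),
                                      {0: 3, 1: 4, 2: 5}))
        clo = network.closeness_centrality(g)
        assert clo[0] == pytest.approx(2.0)   # only its own triangle


class TestConsensus:
    def test_identical_rankings_give_top_k(self):
        scores = {f"g{i}": float(10 - i) for i in range(10)}
        cons = network.top_k_consensus(
            {a: scores for a in network.ALGORITHMS}, k=4)
        assert cons.consensus == sorted(["g0", "g1", "g2", "g3"])

    def test_tie_break_is_lexicographic_and_strict(self):
        scores = {"b": 1.0, "a": 1.0, "c": 1.0}
        assert network.rank_nodes(scores, 2) == ["a", "b"]

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        tables = {a: {f"g{i}": float(rng.random()) for i in range(20)}
                  for a in network.ALGORITHMS}
        fwd = network.top_k_consensus(tables, 5, network.ALGORITHMS)
        rev = network.top_k_consensus(tables, 5,
                                      network.ALGORITHMS[::-1])
        assert fwd.consensus == rev.consensus

    def test_published_hub_lists_intersect_to_key_hubs(self):
        """The four subtypes' consensus hub lists reduce to MAPK1 +
        HSP90AB1 (down) and PIK3CA + PIK3R1 (up)."""
        down = network.key_hub_intersection(
            {s: reference.HUB_GENES[s]["down"] for s in
             reference.SUBTYPES})
        up = network.key_hub_intersection(
            {s: reference.HUB_GENES[s]["up"] for s in reference.SUBTYPES})
        assert down == ["HSP90AB1", "MAPK1"]
        assert up == ["PIK3CA", "PIK3R1"]

    def test_disjoint_inputs_empty(self):
        assert network.key_hub_intersection(
            {"a": ["x"], "b": ["y"]}) == []


class TestPlantedClique:
    def test_clique_members_fill_top_mcc_ranks(self, ppi_pair):
        edges, truth = ppi_pair
        g = network.build_network(edges)
        top = network.rank_nodes(network.mcc(g),
                                 len(truth.planted_clique_members))
        assert set(top) == truth.planted_clique_members
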