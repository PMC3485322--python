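"""Surname-network construction, statistics, hubs, components and export."""

import networkx as nx
import numpy as np
import pytest

from surnamespace import (
    LinkRecord,
    build_network,
    connected_components,
    degree,
    degree_distribution,
    degree_vs_frequency,
    export_graph,
    hubs,
    network_stats,
    read_graphml,
)
from surnamespace.errors import LookupError_, UndefinedStatisticError, ValidationError


def star(n=5, value=0.8):
    return [LinkRecord("Hub", f"Leaf{i}", value) for i in range(1, n)]


class TestBuildNetwork:
    def test_empty_links_give_empty_graph(self):
        assert build_network([]).number_of_nodes() == 0

    def test_nodes_are_incident_surnames(self):
        links = [
            LinkRecord("A", "B", 0.5),
            LinkRecord("B", "C", 0.6),
            LinkRecord("C", "D", 0.7),
        ]
        g = build_network(links, d=0.5)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValidationError):
            build_network([LinkRecord("A", "B", 0.5), LinkRecord("B", "A", 0.6)])

    def test_below_threshold_rejected(self):
        with pytest.raises(ValidationError):
            build_network([LinkRecord("A", "B", 0.4)], d=0.5)

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError):
            build_network([LinkRecord("A", "A", 0.9)])

    def test_isolated_nodes_only_when_requested(self):
        links = [LinkRecord("A", "B", 0.5)]
        assert build_network(links).number_of_nodes() == 2
        g = build_network(links, include_isolated=["Z"])
        assert g.number_of_nodes() == 3 and g.degree["Z"] == 0

    def test_node_attributes_attached(self):
        g = build_network(
            [LinkRecord("A", "B", 0.5)],
            node_attrs={"A": {"bearers": 120, "attribution_region": "k1"}},
        )
        assert g.nodes["A"]["bearers"] == 120


class TestDegreeAndStats:
    def test_star_degrees(self):
        g = build_network(star())
        assert degree(g, "Hub") == 4
        assert degree(g, "Leaf1") == 1

    def test_absent_surname(self):
        with pytest.raises(LookupError_):
            degree(build_network(star()), "Nobody")

    def test_printed_subspace_rows_recomputed(self):
        # published sub-network sizes: (n, m) -> rounded (c, rho)
        for n, m, c, rho in [(1200, 4315, 7.2, 0.006), (877, 3885, 8.9, 0.010), (2429, 8405, 6.9, 0.003)]:
            g = nx.gnm_random_graph(n, m, seed=1)
            stats = network_stats(g).rounded()
            assert stats["c"] == c and stats["rho"] == rho

    def test_complete_graph(self):
        g = build_network(
            [LinkRecord(a, b, 1.0) for a, b in [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]]
        )
        stats = network_stats(g)
        assert stats.c == 3.0 and stats.rho == 1.0

    def test_empty_graph_stats_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            network_stats(nx.Graph())

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("A")
        stats = network_stats(g)
        assert stats.c == 0.0 and stats.rho is None

    def test_subset_induced_subgraph(self):
        g = build_network(star())
        stats = network_stats(g, subset={"Hub", "Leaf1", "Leaf2"})
        assert stats.n == 3 and stats.m == 2

    def test_handshake_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = nx.gnm_random_graph(int(rng.integers(5, 40)), int(rng.integers(0, 60)), seed=int(rng.integers(1e6)))
            stats = network_stats(g)
            assert sum(dict(g.degree).values()) == 2 * stats.m
            hist = degree_distribution(g) if g.number_of_nodes() else {}
            assert sum(k * c for k, c in hist.items()) == 2 * stats.m

    def test_components_additive_stats(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("C", "D", 1.0), LinkRecord("D", "E", 1.0)])
        total = network_stats(g)
        parts = [network_stats(g, subset=c) for c in connected_components(g)]
        assert sum(p.n for p in parts) == total.n
        assert sum(p.m for p in parts) == total.m


class TestDegreeDistribution:
    def test_star(self):
        assert degree_distribution(build_network(star())) == {1: 4, 4: 1}

    def test_isolates(self):
        g = nx.empty_graph(3)
        assert degree_distribution(g) == {0: 3}

    def test_triangle(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("B", "C", 1.0), LinkRecord("A", "C", 1.0)])
        assert degree_distribution(g) == {2: 3}

    def test_empty_graph_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            degree_distribution(nx.Graph())


class TestHubs:
    def test_single_group_top_one(self):
        result = hubs(build_network(star()), top_n=1)
        assert result["all"] == [("Hub", 4)]

    def test_tie_broken_lexicographically(self):
        g = build_network([LinkRecord("A", "Z", 1.0), LinkRecord("B", "Z", 1.0)])
        result = hubs(g, top_n=2)
        assert result["all"] == [("Z", 2), ("A", 1)]

    def test_min_degree_above_max_gives_empty(self):
        assert hubs(build_network(star()), min_degree=99)["all"] == []

    def test_grouping_labels(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("C", "D", 1.0)])
        result = hubs(g, grouping={"A": "west", "B": "west", "C": "east"})
        assert set(result) == {"west", "east", "ungrouped"}
        assert result["ungrouped"] == [("D", 1)]


class TestComponents:
    def test_two_disjoint_edges(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("C", "D", 1.0)])
        comps = connected_components(g)
        assert [len(c) for c in comps] == [2, 2]
        assert comps[0] == {"A", "B"}  # size tie broken by smallest member

    def test_connected_graph_single_component(self):
        assert len(connected_components(build_network(star()))) == 1

    def test_isolates_are_singletons(self):
        g = build_network([LinkRecord("A", "B", 1.0)], include_isolated=["Z"])
        assert {"Z"} in connected_components(g)

    def test_largest_first(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("B", "C", 1.0), LinkRecord("X", "Y", 1.0)])
        assert [len(c) for c in connected_components(g)] == [3, 2]


class TestDegreeVsFrequency:
    def test_monotone_pairing(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("A", "C", 1.0), LinkRecord("B", "C", 1.0), LinkRecord("A", "D", 1.0)])
        degs = {s: g.degree[s] for s in g.nodes}
        totals = {s: 100 * degs[s] for s in g.nodes}
        _, rho = degree_vs_frequency(g, totals)
        assert rho == pytest.approx(1.0)

    def test_reversed_pairing(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("A", "C", 1.0), LinkRecord("A", "D", 1.0)])
        totals = {"A": 1, "B": 100, "C": 200, "D": 300}
        df, rho = degree_vs_frequency(g, totals)
        assert rho < 0

    def test_constant_degree_flagged_undefined(self):
        g = build_network([LinkRecord("A", "B", 1.0), LinkRecord("C", "D", 1.0)])
        df, rho = degree_vs_frequency(g, {"A": 1, "B": 2, "C": 3, "D": 4})
        assert rho is None

    def test_missing_total_rejected(self):
        g = build_network([LinkRecord("A", "B", 1.0)])
        with pytest.raises(ValidationError):
            degree_vs_frequency(g, {"A": 1})


class TestExport:
    @pytest.fixture
    def net(self):
        return build_network(
            [LinkRecord("Novák", "Dvořák", 0.6), LinkRecord("Dvořák", "Čapek", 0.55)],
            node_attrs={
                s: {"bearers": b, "attribution_region": r}
                for s, b, r in [("Novák", 300, "k1"), ("Dvořák", 200, "k1"), ("Čapek", 150, "k2")]
            },
            d=0.5,
        )

    def test_graphml_roundtrip(self, net, tmp_path):
        path = export_graph(net, tmp_path / "net.graphml", "graphml")
        back = read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))
        assert back.nodes["Novák"]["bearers"] == 300
        assert back.nodes["Čapek"]["attribution_region"] == "k2"
        for u, v in net.edges:
            assert back.edges[u, v]["weight"] == net.edges[u, v]["weight"]

    def test_edgelist_row_count(self, net, tmp_path):
        import pandas as pd

        path = export_graph(net, tmp_path / "edges.csv", "edgelist")
        assert len(pd.read_csv(path)) == net.number_of_edges()

    def test_nodetable_contains_degree(self, net, tmp_path):
        import pandas as pd

        path = export_graph(net, tmp_path / "nodes.csv", "nodetable")
        df = pd.read_csv(path).set_index("surname")
        assert df.loc["Dvořák", "degree"] == 2

    def test_empty_graph_refused(self, tmp_path):
        with pytest.raises(ValidationError):
            export_graph(nx.Graph(), tmp_path / "x.graphml")
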