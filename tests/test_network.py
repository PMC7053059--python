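import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dopanet.io_model import Edge, Interactome
from dopanet.network import (
    count_cross_interactions,
    lcc_size,
    network_enrichment_test,
    randomize_network,
)


def union_find_lcc(nodes, edges, members):
    """Brute-force oracle: union–find over the induced subgraph."""
    members = [n for n in nodes if n in members]
    parent = {n: n for n in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        if u in parent and v in parent and u != v:
            parent[find(u)] = find(v)
    if not members:
        return 0
    sizes = {}
    for n in members:
        r = find(n)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


class TestCrossCounts:
    def test_directed_upstream_only_counts_a_to_b(self, tiny_graph):
        assert count_cross_interactions(tiny_graph, {"A"}, {"X", "Y"}, "set_a_upstream") == 1

    def test_undirected_counts_only_undirected_edges(self, tiny_graph):
        assert count_cross_interactions(tiny_graph, {"A"}, {"X", "Y"}, "undirected") == 1

    def test_empty_set_b_gives_zero(self, tiny_graph):
        assert count_cross_interactions(tiny_graph, {"A"}, set(), "set_a_upstream") == 0

    def test_overlapping_sets_error_names_genes(self, tiny_graph):
        with pytest.raises(ValueError, match="A"):
            count_cross_interactions(tiny_graph, {"A"}, {"A", "X"})

    def test_self_loops_never_counted(self):
        g = Interactome(set(), [Edge("A", "A", "t", False), Edge("A", "B", "t", False)])
        assert count_cross_interactions(g, {"A"}, {"B"}) == 1

    def test_type_multiplicity_collapsed(self):
        g = Interactome(
            set(),
            [Edge("A", "B", "t1", False), Edge("A", "B", "t2", False)],
        )
        assert count_cross_interactions(g, {"A"}, {"B"}) == 1

    @given(st.data())
    def test_upstream_downstream_symmetry(self, data):
        n = data.draw(st.integers(3, 8))
        nodes = [f"N{i}" for i in range(n)]
        edges = [
            Edge(nodes[i], nodes[j], "t", True)
            for i in range(n)
            for j in range(n)
            if i != j and data.draw(st.booleans())
        ]
        g = Interactome(set(nodes), edges)
        half = set(nodes[: n // 2])
        rest = set(nodes) - half
        assert count_cross_interactions(
            g, half, rest, "set_a_upstream"
        ) == count_cross_interactions(g, rest, half, "set_a_downstream")


class TestLCC:
    def test_path_plus_isolated_node(self):
        g = Interactome(
            {"A", "B", "C", "D"},
            [Edge("A", "B", "t", False), Edge("B", "C", "t", False)],
        )
        assert lcc_size(g, {"A", "B", "C", "D"}) == 3

    def test_no_induced_edges_gives_one_if_present(self):
        g = Interactome({"A", "B"}, [Edge("A", "B", "t", False)])
        assert lcc_size(g, {"A"}) == 1
        assert lcc_size(g, {"Z"}) == 0

    def test_tie_between_components(self):
        edges = [Edge(a, b, "t", False) for a, b in
                 [("A", "B"), ("B", "C"), ("C", "D"), ("E", "F"), ("F", "G"), ("G", "H")]]
        assert lcc_size(Interactome(set(), edges), set("ABCDEFGH")) == 4

    def test_directed_edges_count_for_connectivity(self):
        g = Interactome(set(), [Edge("A", "B", "t", True)])
        assert lcc_size(g, {"A", "B"}) == 2

    def test_matches_union_find_on_random_small_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            nodes = [f"N{i}" for i in range(n)]
            edges = [
                Edge(nodes[i], nodes[j], "t", bool(rng.integers(2)))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            g = Interactome(set(nodes), edges)
            members = {nd for nd in nodes if rng.random() < 0.7}
            expected = union_find_lcc(
                nodes, [(e.source, e.target) for e in edges], members
            )
            assert lcc_size(g, members) == expected


def four_cycle():
    return Interactome(
        set(),
        [Edge(a, b, "t", False) for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]],
    )


class TestRandomization:
    def test_label_shuffle_preserves_degree_multiset(self):
        rng = np.random.default_rng(3)
        edges = [
            Edge(f"N{i}", f"N{j}", "t", False)
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.4
        ]
        g = Interactome({f"N{i}" for i in range(10)}, edges)
        shuffled = randomize_network(g, "node_label_shuffle", seed=5)

        def degree_multiset(graph):
            deg = {}
            for e in graph.edges:
                deg[e.source] = deg.get(e.source, 0) + 1
                deg[e.target] = deg.get(e.target, 0) + 1
            return sorted(deg.values())

        assert degree_multiset(shuffled) == degree_multiset(g)
        assert shuffled.nodes == g.nodes

    def test_rewire_preserves_degree_sequence(self):
        rng = np.random.default_rng(11)
        edges = [
            Edge(f"N{i}", f"N{j}", "t", False)
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.35
        ]
        g = Interactome({f"N{i}" for i in range(12)}, edges)
        rewired = randomize_network(g, "degree_preserving_rewire", seed=2)

        def degrees(graph):
            deg = {n: 0 for n in graph.nodes}
            for e in graph.edges:
                deg[e.source] += 1
                deg[e.target] += 1
            return deg

        assert degrees(rewired) == degrees(g)
        assert len(rewired.edges) == len(g.edges)
        assert rewired.n_self_loops == 0

    def test_rewired_four_cycle_is_still_a_four_cycle(self):
        g = randomize_network(four_cycle(), "degree_preserving_rewire", seed=4)
        deg = {}
        for e in g.edges:
            deg[e.source] = deg.get(e.source, 0) + 1
            deg[e.target] = deg.get(e.target, 0) + 1
        assert sorted(deg.values()) == [2, 2, 2, 2]
        assert len(g.edges) == 4
        assert lcc_size(g, g.nodes) == 4

    def test_same_seed_gives_identical_output(self):
        g = four_cycle()
        for method in ("degree_preserving_rewire", "node_label_shuffle"):
            a = randomize_network(g, method, seed=9)
            b = randomize_network(g, method, seed=9)
            assert a.edges == b.edges

    def test_impossible_rewire_returns_input_with_warning(self):
        path = Interactome(set(), [Edge("A", "B", "t", False), Edge("B", "C", "t", False)])
        with pytest.warns(UserWarning, match="rewiring"):
            out = randomize_network(path, "degree_preserving_rewire", seed=1)
        assert sorted((e.source, e.target) for e in out.edges) == [("A", "B"), ("B", "C")]


class TestEnrichmentTest:
    def test_observed_zero_gives_p_one(self):
        g = Interactome({"A", "B", "C", "D"}, [Edge("C", "D", "t", False)])
        res = network_enrichment_test(
            g, {"A"}, {"B"}, "ppi_count", "undirected", n_random=50,
            method="node_label_shuffle", seed=0,
        )
        assert res.observed == 0
        assert res.p_empirical == 1.0

    @pytest.mark.parametrize("method", ["node_label_shuffle", "degree_preserving_rewire"])
    def test_identical_seed_identical_result(self, method):
        rng = np.random.default_rng(8)
        edges = [
            Edge(f"N{i}", f"N{j}", "t", False)
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.random() < 0.3
        ]
        g = Interactome({f"N{i}" for i in range(15)}, edges)
        kw = dict(statistic="ppi_count", direction="undirected", n_random=20, seed=42)
        a = network_enrichment_test(g, {"N0", "N1", "N2"}, {"N3", "N4", "N5"}, method=method, **kw)
        b = network_enrichment_test(g, {"N0", "N1", "N2"}, {"N3", "N4", "N5"}, method=method, **kw)
        assert a.to_dict() == b.to_dict()

    def test_zero_spread_null_reports_nan_z(self):
        g = Interactome({"A", "B", "C"}, [Edge("A", "B", "t", False)])
        res = network_enrichment_test(
            g, {"A"}, {"B"}, "lcc_size", n_random=10,
            method="degree_preserving_rewire", seed=0,
        )
        assert np.isnan(res.z)
        assert 0 < res.p_empirical <= 1

    def test_null_length_matches_n_random(self, tiny_graph):
        res = network_enrichment_test(
            tiny_graph, {"A"}, {"Y"}, "ppi_count", "undirected",
            n_random=17, method="node_label_shuffle", seed=3,
        )
        assert res.n_random == len(res.null_values) == 17
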