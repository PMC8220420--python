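"""Communication-graph construction, k-shortest paths against an exhaustive
oracle, and path statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from brr2allo.commgraph import (
    BlockPathStats,
    NoPath,
    ResiduePath,
    aggregate_crossings,
    build_graph,
    interface_crossings,
    k_shortest_paths,
    participation_frequency,
    path_cost,
    path_length_statistics,
    shortest_path,
)
from brr2allo.hbonds import HBondProbabilityMatrix


def _matrix(probs, residues=None):
    probs = {tuple(sorted(k)): v for k, v in probs.items()}
    if residues is None:
        residues = sorted({r for pair in probs for r in pair})
    return HBondProbabilityMatrix(residues, probs, n_frames=100)


def brute_force_k_shortest(graph, source, target, k):
    """Independent oracle: enumerate all simple paths, sort, take k."""
    paths = [
        list(p) for p in nx.all_simple_paths(graph, source, target)
    ]
    paths.sort(key=lambda nodes: (round(path_cost(graph, nodes), 9), len(nodes),
                                  tuple(nodes)))
    return [ResiduePath(tuple(p), path_cost(graph, p)) for p in paths[:k]]


class TestBuildGraph:
    def test_unit_probability_gives_zero_cost(self):
        g = build_graph(_matrix({(("A", 1), ("A", 5)): 1.0}), set())
        assert g[("A", 1)][("A", 5)]["cost"] == 0.0

    def test_half_probability_gives_ln2(self):
        g = build_graph(_matrix({(("A", 1), ("A", 5)): 0.5}), set())
        assert g[("A", 1)][("A", 5)]["cost"] == pytest.approx(np.log(2), rel=1e-12)

    def test_zero_probability_gives_no_edge(self):
        m = HBondProbabilityMatrix([("A", 1), ("A", 5)], {}, 100)
        g = build_graph(m, set())
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_covalent_edge_overrides_hbond_cost(self):
        adj = {(("A", 1), ("A", 2))}
        g = build_graph(_matrix({(("A", 1), ("A", 2)): 0.5}), adj)
        assert g[("A", 1)][("A", 2)]["cost"] == 0.0
        assert g[("A", 1)][("A", 2)]["provenance"] == "covalent"
        assert g[("A", 1)][("A", 2)]["probability"] == 0.5


def _random_graph(rng, n_nodes):
    g = nx.Graph()
    nodes = [("A", i) for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        u = rng.random()
        if u < 0.25:
            g.add_edge(a, b, cost=0.0, provenance="covalent")
        elif u < 0.6:
            p = rng.uniform(0.05, 1.0)
            g.add_edge(a, b, cost=-np.log(p), probability=p, provenance="hbond")
    return g, nodes


class TestKShortestPaths:
    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            g, nodes = _random_graph(rng, int(rng.integers(4, 9)))
            s, t = nodes[0], nodes[-1]
            expected = brute_force_k_shortest(g, s, t, 5)
            got = k_shortest_paths(g, s, t, 5)
            if not expected:
                assert isinstance(got, NoPath)
                continue
            checked += 1
            assert [p.residues for p in got] == [p.residues for p in expected]
            for p in got:
                assert p.cost == pytest.approx(
                    path_cost(g, list(p.residues)), abs=1e-12
                )
        assert checked > 50

    def test_k1_equals_shortest_path(self):
        rng = np.random.default_rng(7)
        g, nodes = _random_graph(rng, 7)
        sp = shortest_path(g, nodes[0], nodes[-1])
        k1 = k_shortest_paths(g, nodes[0], nodes[-1], 1)
        if isinstance(sp, NoPath):
            assert isinstance(k1, NoPath)
        else:
            assert k1[0].residues == sp.residues

    def test_parallel_ladder_returns_all_three_paths(self):
        g = nx.Graph()
        s, t = ("A", 1), ("A", 9)
        for i, p in enumerate((0.9, 0.5, 0.2)):
            mid = ("A", 2 + i)
            g.add_edge(s, mid, cost=-np.log(p), provenance="hbond")
            g.add_edge(mid, t, cost=-np.log(p), provenance="hbond")
        paths = k_shortest_paths(g, s, t, 10)
        assert len(paths) == 3
        assert [p.residues[1] for p in paths] == [("A", 2), ("A", 3), ("A", 4)]

    def test_all_covalent_chain_costs_zero(self):
        g = nx.Graph()
        nodes = [("A", i) for i in range(5)]
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b, cost=0.0, provenance="covalent")
        sp = shortest_path(g, nodes[0], nodes[-1])
        assert sp.cost == 0.0
        assert sp.residues == tuple(nodes)

    def test_disconnected_pair_yields_explicit_no_path(self):
        g = nx.Graph()
        g.add_node(("A", 1))
        g.add_node(("A", 2))
        assert isinstance(shortest_path(g, ("A", 1), ("A", 2)), NoPath)

    def test_deterministic_under_equal_costs(self):
        # two zero-cost routes; lexicographic tie-break must pick the same
        g = nx.Graph()
        s, t = ("A", 1), ("A", 4)
        for mid in (("A", 2), ("A", 3)):
            g.add_edge(s, mid, cost=0.0, provenance="covalent")
            g.add_edge(mid, t, cost=0.0, provenance="covalent")
        first = [k_shortest_paths(g, s, t, 2)[0].residues for _ in range(5)]
        assert all(f == ((("A", 1), ("A", 2), ("A", 4))) for f in first)

    def test_raising_edge_probability_never_increases_cost(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g, nodes = _random_graph(rng, 6)
            s, t = nodes[0], nodes[-1]
            base = shortest_path(g, s, t)
            hedges = [
                (u, v) for u, v, d in g.edges(data=True) if d["provenance"] == "hbond"
            ]
            if isinstance(base, NoPath) or not hedges:
                continue
            u, v = hedges[int(rng.integers(len(hedges)))]
            p = g[u][v]["probability"]
            g[u][v].update(probability=min(1.0, p * 2), cost=-np.log(min(1.0, p * 2)))
            after = shortest_path(g, s, t)
            assert after.cost <= base.cost + 1e-12


class TestPathStatistics:
    def _path(self, *resnums, cost=0.0):
        return ResiduePath(tuple(("A", r) for r in resnums), cost)

    def test_single_path_participation_all_one(self):
        freq = participation_frequency([self._path(1, 2, 3)])
        assert set(freq.values()) == {1.0}

    def test_shared_interior_residue_frequency(self):
        freq = participation_frequency(
            [self._path(1, 2, 3, 5), self._path(1, 4, 3, 5)]
        )
        assert freq[("A", 3)] == 1.0
        assert freq[("A", 2)] == 0.5
        assert freq[("A", 4)] == 0.5

    def test_identical_blocks_give_zero_sem(self):
        blocks = [[self._path(1, 2, 3)] for _ in range(5)]
        stats = path_length_statistics(blocks)
        assert stats.mean_length == 3.0
        assert stats.sem_length == 0.0

    def test_alternating_block_lengths_average(self):
        blocks = [
            [self._path(*range(1, 6))],
            [self._path(*range(1, 8))],
        ] * 2
        stats = path_length_statistics(blocks)
        assert stats.mean_length == 6.0

    def test_single_block_sem_undefined(self):
        stats = path_length_statistics([[self._path(1, 2)]])
        assert stats.sem_length is None
        assert stats.n_blocks_used == 1

    def test_pathless_blocks_excluded_and_reported(self):
        blocks = [[self._path(1, 2, 3)], NoPath(("A", 1), ("A", 3)), []]
        stats = path_length_statistics(blocks)
        assert stats.excluded_blocks == [1, 2]
        assert stats.n_blocks_used == 1


class TestInterfaceCrossings:
    def _path_of(self, resnums):
        return ResiduePath(tuple(("A", r) for r in resnums), 0.0)

    def test_path_within_one_cassette_has_no_crossings(self):
        assert interface_crossings(self._path_of([500, 501, 502])) == []

    def test_single_crossing_identified(self):
        path = self._path_of([602, 603, 1575, 1576])
        assert interface_crossings(path) == [(("A", 603), ("A", 1575))]

    def test_zigzag_counts_each_crossing(self):
        path = self._path_of([500, 1300, 501, 1301])
        assert len(interface_crossings(path)) == 3

    def test_aggregate_tally(self):
        paths = [self._path_of([603, 1575]), self._path_of([602, 603, 1575])]
        tally = aggregate_crossings(paths)
        assert tally[(("A", 603), ("A", 1575))] == 2

    def test_unpartitioned_residue_raises(self):
        path = self._path_of([500, 1300])
        with pytest.raises(ValueError):
            interface_crossings(path, partition=lambda r: "??")


def test_path_cost_additivity():
    rng = np.random.default_rng(42)
    g, nodes = _random_graph(rng, 8)
    result = k_shortest_paths(g, nodes[0], nodes[-1], 10)
    if isinstance(result, NoPath):
        pytest.skip("random graph disconnected for this seed")
    for p in result:
        recomputed = sum(
            g[u][v]["cost"] for u, v in zip(p.residues, p.residues[1:])
        )
        assert p.cost == pytest.approx(recomputed, abs=1e-12)
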