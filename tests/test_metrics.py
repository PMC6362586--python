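"""Structural characteristics against exhaustive brute-force oracles."""
import math

import networkx as nx
import numpy as np
import pytest

import tissuenet.bruteforce as bf
from tissuenet import metrics as m
from tissuenet.kb_model import BioNode, Interaction
from tissuenet.reconstruct import GeneNetwork


def graph(edges, isolated=()):
    vertices = {v for e in edges for v in e} | set(isolated)
    return m.SimpleGraph.from_edges(vertices, edges)


K3 = graph([("a", "b"), ("b", "c"), ("a", "c")])
PATH3 = graph([("a", "b"), ("b", "c")])
STAR4 = graph([("h", "l1"), ("h", "l2"), ("h", "l3")])
CYCLE4 = graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
EMPTY = graph([])


class TestProjection:
    def test_antiparallel_pair_collapses(self):
        net = GeneNetwork(
            "x",
            {"g1": BioNode("g1", "gene"), "p1": BioNode("p1", "protein")},
            (
                Interaction("g1", "p1", "expression", True),
                Interaction("p1", "g1", "regulation", True),
            ),
        )
        g = m.project(net)
        assert g.n_edges == 1

    def test_empty_network(self):
        net = GeneNetwork("x", {}, ())
        assert m.project(net).n_vertices == 0

    def test_triangle_with_duplicate_edge(self):
        g = m.SimpleGraph.from_edges(
            "abc", [("a", "b"), ("b", "c"), ("a", "c"), ("a", "b")]
        )
        assert g.n_edges == 3


@pytest.mark.parametrize(
    "g,expected",
    [(K3, 1.0), (PATH3, 0.0), (STAR4, 0.0), (EMPTY, 0.0)],
)
def test_clustering_examples(g, expected):
    assert m.clustering_coefficient(g) == pytest.approx(expected)


@pytest.mark.parametrize(
    "g,expected",
    [
        (graph([("a", "b"), ("b", "c"), ("a", "c")], isolated=["z"]), 2),
        (EMPTY, 0),
        (PATH3, 1),
    ],
)
def test_component_counts(g, expected):
    assert m.count_components(g) == expected


@pytest.mark.parametrize(
    "g,expected",
    [(STAR4, 1.0), (CYCLE4, 0.0), (K3, 0.0), (PATH3, pytest.approx(1.0))],
)
def test_centralization_examples(g, expected):
    assert m.centralization(g) == expected


@pytest.mark.parametrize(
    "g,expected",
    [
        (PATH3, 6),   # one geodesic per ordered pair
        (CYCLE4, 16),  # 8 adjacent ordered pairs x1 + 4 antipodal x2
        (K3, 6),
        (EMPTY, 0),
    ],
)
def test_shortest_path_counts(g, expected):
    assert m.count_shortest_paths(g) == expected


def test_shortest_path_pairs_only_mode():
    assert m.count_shortest_paths(CYCLE4, pairs_only=True) == 12


@pytest.mark.parametrize(
    "g,expected", [(K3, 2.0), (STAR4, 1.5), (EMPTY, 0.0)]
)
def test_avg_neighbors_examples(g, expected):
    assert m.avg_neighbors(g) == expected


@pytest.mark.parametrize(
    "g,expected",
    [(K3, 1.0), (graph([], isolated="abc"), 0.0), (EMPTY, 0.0)],
)
def test_density_examples(g, expected):
    assert m.density(g) == expected


def test_heterogeneity_examples():
    assert m.heterogeneity(CYCLE4) == 0.0  # regular graph
    # star 1+3: degrees 3,1,1,1 -> sqrt(0.75)/1.5
    assert m.heterogeneity(STAR4) == pytest.approx(math.sqrt(0.75) / 1.5)


def test_betweenness_examples():
    bw = m.betweenness(PATH3)
    assert bw["b"] == pytest.approx(1.0)
    assert bw["a"] == bw["c"] == 0.0
    assert m.betweenness(STAR4)["h"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def random_graphs():
    rng = np.random.default_rng(1234)
    graphs = []
    for _ in range(220):
        n = int(rng.integers(0, 13))
        p = rng.random() * 0.6
        graphs.append(bf.random_adjacency(rng, n, p))
    return graphs


class TestOracleEquivalence:
    """Every metric equals its exhaustive brute-force oracle on random graphs."""

    def test_all_metrics_match_bruteforce(self, random_graphs):
        for adj in random_graphs:
            g = m.SimpleGraph(adj)
            assert m.clustering_coefficient(g) == pytest.approx(bf.clustering(adj), abs=1e-12)
            assert m.clustering_coefficient(g, all_nodes=True) == pytest.approx(
                bf.clustering(adj, all_nodes=True), abs=1e-12
            )
            assert m.count_components(g) == bf.components(adj)
            assert m.centralization(g) == pytest.approx(bf.centralization(adj), abs=1e-12)
            assert m.count_shortest_paths(g) == bf.count_shortest_paths(adj)
            assert m.count_shortest_paths(g, pairs_only=True) == bf.count_shortest_paths(
                adj, pairs_only=True
            )
            assert m.avg_neighbors(g) == pytest.approx(bf.avg_neighbors(adj), abs=1e-12)
            assert m.density(g) == pytest.approx(bf.density(adj), abs=1e-12)
            assert m.heterogeneity(g) == pytest.approx(bf.heterogeneity(adj), abs=1e-12)

    def test_betweenness_matches_geodesic_enumeration(self, random_graphs):
        for adj in random_graphs[:120]:
            g = m.SimpleGraph(adj)
            ours = m.betweenness(g)
            oracle = bf.betweenness(adj)
            assert max(
                (abs(ours[v] - oracle[v]) for v in adj), default=0.0
            ) < 1e-10

    def test_raw_betweenness_matches_unnormalized_accumulation(self, random_graphs):
        for adj in random_graphs[:60]:
            g = m.SimpleGraph(adj)
            ours = m.betweenness(g, normalized=False)
            oracle = bf.betweenness(adj, normalized=False)
            assert max(
                (abs(ours[v] - oracle[v]) for v in adj), default=0.0
            ) < 1e-10

    def test_density_edge_count_identity(self, random_graphs):
        for adj in random_graphs:
            g = m.SimpleGraph(adj)
            n = g.n_vertices
            if n >= 2:
                assert m.density(g) * n * (n - 1) / 2 == pytest.approx(g.n_edges)


class TestCharacterize:
    def test_k3_record(self):
        c = m.characterize(K3)
        assert (
            c.n_nodes,
            c.clustering,
            c.n_components,
            c.centralization,
            c.n_shortest_paths,
            c.avg_neighbors,
            c.density,
            c.heterogeneity,
        ) == (3, 1.0, 1, 0.0, 6, 2.0, 1.0, 0.0)

    def test_empty_record_degenerate(self):
        c = m.characterize(EMPTY)
        assert c.degenerate
        assert all(v == 0 for v in c.as_dict().values())

    def test_relabeling_invariance(self, rng):
        adj = bf.random_adjacency(rng, 10, 0.3)
        g = m.SimpleGraph(adj)
        mapping = {v: f"node_{i}" for i, v in enumerate(sorted(adj, key=lambda v: hash(v)))}
        relabeled = m.SimpleGraph(
            {mapping[v]: {mapping[u] for u in ns} for v, ns in adj.items()}
        )
        a, b = m.characterize(g), m.characterize(relabeled)
        for k, v in a.as_dict().items():
            assert getattr(b, k) == pytest.approx(v, abs=1e-12), k

    def test_worked_fixture_frozen_records(self, fixture_kb, fixture_catalog, fixture_combined):
        from tissuenet.synthetic_data import (
            WORKED_COMBINED_CHARACTERISTICS,
            WORKED_T1_CHARACTERISTICS,
        )
        import tissuenet as tn

        got = m.characterize(fixture_combined)
        for k, v in WORKED_COMBINED_CHARACTERISTICS.as_dict().items():
            assert getattr(got, k) == pytest.approx(v, abs=1e-12), k
        t1 = tn.filter_by_tissue(fixture_combined, fixture_catalog, "T1")
        got = m.characterize(t1)
        for k, v in WORKED_T1_CHARACTERISTICS.as_dict().items():
            assert getattr(got, k) == pytest.approx(v, abs=1e-12), k

    def test_isolated_vertex_monotonicity(self, rng):
        for _ in range(20):
            adj = bf.random_adjacency(rng, int(rng.integers(2, 10)), rng.random())
            g = m.SimpleGraph(adj)
            bigger = m.SimpleGraph({**{k: set(v) for k, v in adj.items()}, "zzz_iso": set()})
            a, b = m.characterize(g), m.characterize(bigger)
            assert b.n_nodes == a.n_nodes + 1
            assert b.n_components == a.n_components + 1
            assert b.density <= a.density
            assert b.avg_neighbors <= a.avg_neighbors
            assert b.clustering <= a.clustering + 1e-12

    def test_betweenness_sum_vs_brandes_accumulation(self, rng):
        """Normalized values times (n-1)(n-2)/2 equal the raw Brandes scores."""
        for _ in range(20):
            adj = bf.random_adjacency(rng, int(rng.integers(3, 11)), 0.4)
            g = m.SimpleGraph(adj)
            n = g.n_vertices
            norm = (n - 1) * (n - 2) / 2
            normed = m.betweenness(g)
            raw = m.betweenness(g, normalized=False)
            for v in adj:
                assert normed[v] * norm == pytest.approx(raw[v], abs=1e-9)
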