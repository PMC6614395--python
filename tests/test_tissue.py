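import itertools
import math

import networkx as nx
import numpy as np
import pytest

from targetrank.errors import ValidationError
from targetrank.tissue import (
    UNREACHABLE,
    DiseaseGeneWeights,
    TissueInteractome,
    build_tissue_subnetwork,
    dijkstra_cost,
    disease_gene_weights,
    scale_expression,
    score_tissue_targets,
    tissue_score,
    to_edge_weighted,
)


def _interactome(z, edges, tissue="t"):
    g = nx.Graph()
    for node, zv in z.items():
        g.add_node(node, z=zv)
    g.add_edges_from(edges)
    return TissueInteractome(tissue=tissue, graph=g)


def enumerate_min_cost(graph, source, target):
    """Oracle: cheapest cost over all simple paths, by explicit DFS."""
    best = math.inf

    def dfs(node, cost, visited):
        nonlocal best
        if node == target:
            best = min(best, cost)
            return
        for _, nxt, data in graph.out_edges(node, data=True):
            if nxt not in visited:
                dfs(nxt, cost + data["cost"], visited | {nxt})

    dfs(source, 0.0, {source})
    return best


class TestSubnetwork:
    def test_threshold_filter_keeps_active_genes(self):
        it = _interactome({"A": 1.2, "B": 0.5, "C": 2.0}, [("A", "B"), ("A", "C")])
        sub = build_tissue_subnetwork(it, 1.0)
        assert set(sub.graph.nodes) == {"A", "C"}
        assert list(sub.graph.edges) == [("A", "C")]

    def test_absent_expression_is_excluded(self):
        it = _interactome({"A": 2.0, "B": None}, [("A", "B")])
        sub = build_tissue_subnetwork(it, 1.0)
        assert set(sub.graph.nodes) == {"A"}

    def test_minus_infinity_threshold_is_identity_on_measured_genes(self):
        it = _interactome({"A": -5.0, "B": 0.0}, [("A", "B")])
        sub = build_tissue_subnetwork(it, -math.inf)
        assert set(sub.graph.nodes) == {"A", "B"}

    def test_all_below_threshold_warns_and_returns_empty(self):
        it = _interactome({"A": 0.1, "B": 0.2}, [("A", "B")])
        with pytest.warns(UserWarning):
            sub = build_tissue_subnetwork(it, 1.0)
        assert sub.graph.number_of_nodes() == 0

    def test_raising_threshold_never_adds_nodes_or_edges(self):
        rng = np.random.default_rng(5)
        z = {f"n{i}": float(rng.normal()) for i in range(30)}
        edges = [
            (f"n{a}", f"n{b}")
            for a, b in rng.integers(0, 30, size=(60, 2))
            if a != b
        ]
        it = _interactome(z, edges)
        prev_nodes, prev_edges = None, None
        for thr in (-1.0, 0.0, 0.5, 1.0, 2.0):
            sub = build_tissue_subnetwork(it, thr)
            nodes, eds = set(sub.graph.nodes), set(map(frozenset, sub.graph.edges))
            if prev_nodes is not None:
                assert nodes <= prev_nodes and eds <= prev_edges
            prev_nodes, prev_edges = nodes, eds


class TestScaleExpression:
    def test_minmax(self):
        assert scale_expression({"A": 1, "B": 2, "C": 3}) == {
            "A": 0.0, "B": 0.5, "C": 1.0,
        }

    def test_constant_maps_to_half(self):
        assert scale_expression({"A": 2, "B": 2}) == {"A": 0.5, "B": 0.5}
        assert scale_expression({"A": 7}) == {"A": 0.5}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            scale_expression({})


class TestEdgeWeighting:
    def test_cost_is_one_minus_destination_expression(self):
        it = _interactome({"A": 3.0, "B": 1.0}, [("A", "B")])
        g = to_edge_weighted(it, {"A": 1.0, "B": 0.2}, disease_genes=set())
        assert g["A"]["B"]["cost"] == pytest.approx(0.8)
        assert g["B"]["A"]["cost"] == pytest.approx(0.0)

    def test_edge_into_disease_gene_priced_by_source(self):
        it = _interactome({"A": 3.0, "B": 1.0}, [("A", "B")])
        g = to_edge_weighted(it, {"A": 1.0, "B": 0.2}, disease_genes={"B"})
        assert g["A"]["B"]["cost"] == pytest.approx(0.0)  # w(A)
        assert g["B"]["A"]["cost"] == pytest.approx(0.0)  # A not in D -> w(A)

    def test_raw_cost_mode_uses_scaled_expression_directly(self):
        it = _interactome({"A": 3.0, "B": 1.0}, [("A", "B")])
        g = to_edge_weighted(it, {"A": 1.0, "B": 0.2}, set(), invert=False)
        assert g["A"]["B"]["cost"] == pytest.approx(0.2)

    def test_missing_scaled_value_rejected(self):
        it = _interactome({"A": 3.0, "B": 1.0}, [("A", "B")])
        with pytest.raises(ValidationError):
            to_edge_weighted(it, {"A": 1.0}, set())


class TestDijkstra:
    def test_three_node_worked_example(self):
        g = nx.DiGraph()
        g.add_edge("s", "a", cost=0.2)
        g.add_edge("a", "t", cost=0.3)
        g.add_edge("s", "t", cost=0.9)
        assert dijkstra_cost(g, "s", "t") == pytest.approx(0.5)
        assert dijkstra_cost(g, "s", "s") == 0

    def test_unreachable_gives_sentinel(self):
        g = nx.DiGraph()
        g.add_node("x")
        g.add_edge("s", "a", cost=0.1)
        assert dijkstra_cost(g, "s", "x") == UNREACHABLE
        with pytest.raises(ValidationError):
            dijkstra_cost(g, "s", "zzz")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for a, b in itertools.permutations(range(n), 2):
            if rng.random() < 0.35:
                g.add_edge(a, b, cost=float(rng.uniform(0, 1)))
        for s, t in itertools.permutations(range(n), 2):
            assert dijkstra_cost(g, s, t) == pytest.approx(
                enumerate_min_cost(g, s, t)
            )


class TestDiseaseGeneWeights:
    def test_unanimous_centrality_gives_bucketed_levels(self):
        # path graph: middle nodes are more central than the tips
        z = {f"n{i}": 1.0 + 0.01 * i for i in range(9)}
        edges = [(f"n{i}", f"n{i+1}") for i in range(8)]
        it = _interactome(z, edges)
        w = disease_gene_weights(it, set(z))
        assert sorted(w.c.values()) == [0.25] * 3 + [0.5] * 3 + [0.75] * 3
        # the two tips are least central
        assert w.c["n0"] == 0.25 and w.c["n8"] == 0.25

    def test_fewer_than_three_genes_all_get_half(self):
        it = _interactome({"A": 1.0, "B": 2.0}, [("A", "B")])
        assert disease_gene_weights(it, {"A"}).c == {"A": 0.5}
        assert disease_gene_weights(it, {"A", "B"}).c == {"A": 0.5, "B": 0.5}

    def test_no_disease_gene_in_subnetwork_rejected(self):
        it = _interactome({"A": 1.0}, [])
        with pytest.raises(ValidationError):
            disease_gene_weights(it, {"Z"})


class TestTissueScore:
    def test_weighted_average_worked_example(self):
        g = nx.DiGraph()
        g.add_edge("g", "d1", cost=0.4)
        g.add_edge("g", "d2", cost=0.8)
        w = DiseaseGeneWeights(D={"d1", "d2"}, c={"d1": 0.5, "d2": 0.75})
        tss, cov = tissue_score(w, g, "g")
        assert tss == pytest.approx(-(0.5 * 0.4 + 0.75 * 0.8) / 2)
        assert tss == pytest.approx(-0.4)
        assert cov == 1.0

    def test_unreachable_disease_genes_are_renormalized_out(self):
        g = nx.DiGraph()
        g.add_edge("g", "d1", cost=0.4)
        g.add_node("d2")
        w = DiseaseGeneWeights(D={"d1", "d2"}, c={"d1": 0.5, "d2": 0.75})
        tss, cov = tissue_score(w, g, "g")
        assert tss == pytest.approx(-0.5 * 0.4)
        assert cov == 0.5

    def test_disease_gene_scoring_itself_at_zero_cost(self):
        g = nx.DiGraph()
        g.add_node("d1")
        w = DiseaseGeneWeights(D={"d1"}, c={"d1": 0.5})
        assert tissue_score(w, g, "d1") == (0.0, 1.0)

    def test_nothing_reachable_gives_absent(self):
        g = nx.DiGraph()
        g.add_node("g")
        g.add_node("d1")
        w = DiseaseGeneWeights(D={"d1"}, c={"d1": 0.5})
        tss, cov = tissue_score(w, g, "g")
        assert tss is None and cov == 0.0

    def test_decreasing_an_edge_cost_never_decreases_tss(self):
        rng = np.random.default_rng(3)
        z = {f"n{i}": float(rng.uniform(1, 3)) for i in range(12)}
        edges = {
            tuple(sorted((f"n{a}", f"n{b}")))
            for a, b in rng.integers(0, 12, size=(30, 2))
            if a != b
        }
        it = _interactome(z, sorted(edges))
        D = {"n0", "n1", "n2"}
        from targetrank.tissue import scale_expression as scale

        scaled = scale(z)
        g = to_edge_weighted(it, scaled, D)
        w = disease_gene_weights(it, D)
        before = {n: tissue_score(w, g, n)[0] for n in z}
        u, v = next(iter(g.edges))
        g[u][v]["cost"] *= 0.5
        after = {n: tissue_score(w, g, n)[0] for n in z}
        for n in z:
            if before[n] is not None:
                assert after[n] >= before[n] - 1e-12


def test_score_tissue_targets_end_to_end_shapes(default_world):
    d = "D00"
    it = [
        i for i in default_world.interactomes()
        if i.tissue == default_world.disease_tissue[d]
    ][0]
    df = score_tissue_targets(it, default_world.disease_genes[d])
    assert set(df.columns) == {"gene_id", "tissue", "tss", "coverage"}
    scored = df.dropna(subset=["tss"])
    assert (scored["tss"] <= 1e-12).all()
    assert scored["coverage"].between(0, 1).all()
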