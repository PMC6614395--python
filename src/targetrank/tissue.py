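"""Tissue-specific efficacy score (TSS).

The score asks how cheaply a candidate target reaches the known disease
genes inside a tissue-active subnetwork of the interactome. A tissue's
subnetwork I_t keeps the genes whose expression significance z_E meets a
threshold (default 1.0). Expression z-scores are min-max scaled to [0, 1]
and turned into traversal costs w(x) = 1 - scaled(x), so paths through
highly tissue-specific genes are cheap. Each undirected interaction {A, B}
becomes two directed edges; the edge into a node is priced by that node's
expression, except that edges into a disease gene are priced by the node
they come from (the destination's own expression should not discount the
final hop).

The per-target score is the negated weighted mean of Dijkstra shortest-path
costs to the disease genes, weighted by a discretized centrality level
c(d) in {0.25, 0.5, 0.75} obtained by Borda-aggregating degree, weighted
betweenness and weighted clustering ranks of the disease genes and cutting
the aggregate ranking into three equal buckets. TSS <= 0 with 0 the best
attainable value; unreachable disease genes are dropped from the average
and reported via a coverage fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "TissueInteractome",
    "DiseaseGeneWeights",
    "build_tissue_subnetwork",
    "scale_expression",
    "to_edge_weighted",
    "dijkstra_cost",
    "disease_gene_weights",
    "tissue_score",
    "score_tissue_targets",
    "weighted_centralities",
    "UNREACHABLE",
]

#: sentinel cost for a target that cannot be reached
UNREACHABLE = math.inf


@dataclass
class TissueInteractome:
    """An undirected gene network with per-gene expression significance.

    Node attribute ``z`` holds z_E (float) or None when the gene has no
    expression measurement in this tissue.
    """

    tissue: str
    graph: nx.Graph

    @property
    def z(self) -> dict[str, float | None]:
        return {n: self.graph.nodes[n].get("z") for n in self.graph.nodes}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class DiseaseGeneWeights:
    """Disease genes present in a subnetwork with centrality levels c(d)."""

    D: set[str]
    c: dict[str, float] = field(default_factory=dict)


def build_tissue_subnetwork(
    interactome: TissueInteractome, z_threshold: float = 1.0
) -> TissueInteractome:
    """Induced subgraph on genes with z_E >= threshold.

    Genes with an absent z_E are excluded; isolated nodes are retained.
    An empty result is returned with a warning rather than an error.
    """
    if not math.isfinite(z_threshold) and z_threshold > 0:
        raise ValidationError("z_threshold must be finite or -inf")
    keep = [
        n
        for n, data in interactome.graph.nodes(data=True)
        if data.get("z") is not None and data["z"] >= z_threshold
    ]
    sub = interactome.graph.subgraph(keep).copy()
    if sub.number_of_nodes() == 0:
        warnings.warn(
            f"tissue {interactome.tissue!r}: no gene passes z_E >= {z_threshold}",
            stacklevel=2,
        )
    return TissueInteractome(tissue=interactome.tissue, graph=sub)


def scale_expression(z_values: Mapping[str, float]) -> dict[str, float]:
    """Min-max scale z-scores to [0, 1] over a subnetwork's genes.

    Constant input maps every gene to 0.5.
    """
    if not z_values:
        raise ValidationError("scale_expression: empty input")
    vals = {g: float(v) for g, v in z_values.items()}
    lo, hi = min(vals.values()), max(vals.values())
    if hi == lo:
        return {g: 0.5 for g in vals}
    return {g: (v - lo) / (hi - lo) for g, v in vals.items()}


def to_edge_weighted(
    subnetwork: TissueInteractome,
    scaled: Mapping[str, float],
    disease_genes: Iterable[str],
    invert: bool = True,
) -> nx.DiGraph:
    """Turn the node-weighted subnetwork into an edge-weighted digraph.

    With ``invert`` (default) the traversal cost of a node is
    w(x) = 1 - scaled(x), so highly expressed genes are cheap to pass
    through; ``invert=False`` uses the scaled expression itself as cost.
    For an edge {A, B}: cost(A->B) = w(B) unless B is a disease gene, in
    which case cost(A->B) = w(A) (and symmetrically for B->A).
    """
    D = set(disease_genes)
    missing = [n for n in subnetwork.graph.nodes if n not in scaled]
    if missing:
        raise ValidationError(f"nodes without a scaled value: {missing[:5]}")

    def w(x: str) -> float:
        s = float(scaled[x])
        return 1.0 - s if invert else s

    g = nx.DiGraph()
    g.add_nodes_from(subnetwork.graph.nodes)
    for a, b in subnetwork.graph.edges:
        g.add_edge(a, b, cost=w(a) if b in D else w(b))
        g.add_edge(b, a, cost=w(b) if a in D else w(a))
    return g


def dijkstra_cost(graph: nx.DiGraph, source: str, target: str) -> float:
    """Minimal directed path cost; UNREACHABLE (inf) when no path exists."""
    for node, name in ((source, "source"), (target, "target")):
        if node not in graph:
            raise ValidationError(f"{name} {node!r} not in graph")
    try:
        return nx.dijkstra_path_length(graph, source, target, weight="cost")
    except nx.NetworkXNoPath:
        return UNREACHABLE


def weighted_centralities(
    subnetwork: TissueInteractome,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Degree, weighted betweenness and weighted clustering per gene.

    Edge distances for betweenness are the mean traversal cost of the two
    endpoints (1 - scaled expression); clustering uses the complementary
    proximity weight so that strongly expressed triangles count more.
    """
    g = subnetwork.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty subnetwork")
    zmap = {n: g.nodes[n].get("z") for n in g.nodes}
    if any(v is None for v in zmap.values()):
        raise ValidationError("subnetwork has genes without expression values")
    scaled = scale_expression(zmap)
    h = g.copy()
    for u, v in h.edges:
        cost = 1.0 - 0.5 * (scaled[u] + scaled[v])
        h[u][v]["cost"] = cost
        h[u][v]["prox"] = 1.0 - cost
    degree = {n: float(d) for n, d in h.degree()}
    betweenness = nx.betweenness_centrality(h, weight="cost", normalized=True)
    clustering = nx.clustering(h, weight="prox")
    return degree, betweenness, clustering


def _borda_order(
    genes: Sequence[str], metrics: Sequence[Mapping[str, float]]
) -> list[str]:
    """Rank genes by each metric (higher = more central = rank 1), sum rank
    positions, return genes most-central-first.

    Within a metric, tied genes share the same (competition) rank so that a
    metric with no resolution — e.g. clustering on a triangle-free graph —
    cannot distort the aggregate; ties in the Borda sum itself are broken
    lexicographically for determinism.
    """
    from scipy.stats import rankdata

    genes = list(genes)
    borda = np.zeros(len(genes))
    for metric in metrics:
        vals = np.array([metric.get(g, 0.0) for g in genes])
        borda += rankdata(-vals, method="min")
    order = sorted(zip(borda, genes))
    return [g for _, g in order]


def disease_gene_weights(
    subnetwork: TissueInteractome, disease_genes: Iterable[str]
) -> DiseaseGeneWeights:
    """Assign c(d) in {0.25, 0.5, 0.75} to the disease genes in a subnetwork.

    Disease genes are ranked by degree, weighted betweenness and weighted
    clustering, Borda-aggregated, and the aggregate ranking is cut into
    three equal-sized buckets: most central third -> 0.75, middle -> 0.5,
    least central -> 0.25. Fewer than three genes all get 0.5.
    """
    present = sorted(set(disease_genes) & set(subnetwork.graph.nodes))
    if not present:
        raise ValidationError("no disease gene present in the subnetwork")
    if len(present) < 3:
        return DiseaseGeneWeights(D=set(present), c={d: 0.5 for d in present})
    metrics = weighted_centralities(subnetwork)
    order = _borda_order(present, metrics)
    n = len(order)
    levels = (0.75, 0.5, 0.25)
    c = {d: levels[i * 3 // n] for i, d in enumerate(order)}
    return DiseaseGeneWeights(D=set(present), c=c)


def tissue_score(
    weights: DiseaseGeneWeights, graph: nx.DiGraph, gene: str
) -> tuple[float | None, float]:
    """TSS(D, I_t, g) and the fraction of disease genes reached.

    TSS = -(1/|reachable D|) * sum over reachable d of c(d) * cost(g -> d).
    Unreachable disease genes are excluded and the divisor shrinks
    accordingly; a target reaching no disease gene gets an absent score.
    """
    if gene not in graph:
        return None, 0.0
    dist = nx.single_source_dijkstra_path_length(graph, gene, weight="cost")
    terms = [weights.c[d] * dist[d] for d in weights.c if d in dist]
    coverage = len(terms) / len(weights.c) if weights.c else 0.0
    if not terms:
        return None, coverage
    return -sum(terms) / len(terms), coverage


def score_tissue_targets(
    interactome: TissueInteractome,
    disease_genes: Iterable[str],
    targets: Iterable[str] | None = None,
    z_threshold: float = 1.0,
    invert: bool = True,
) -> pd.DataFrame:
    """End-to-end TSS for every target gene in one tissue.

    Returns a DataFrame (gene_id, tissue, tss, coverage); genes outside the
    tissue subnetwork or reaching no disease gene get an absent tss.
    """
    sub = build_tissue_subnetwork(interactome, z_threshold)
    if sub.graph.number_of_nodes() == 0:
        cols = ["gene_id", "tissue", "tss", "coverage"]
        return pd.DataFrame(columns=cols)
    scaled = scale_expression({n: sub.graph.nodes[n]["z"] for n in sub.graph.nodes})
    weights = disease_gene_weights(sub, disease_genes)
    graph = to_edge_weighted(sub, scaled, weights.D, invert=invert)
    genes = sorted(targets) if targets is not None else sorted(sub.graph.nodes)
    rows = []
    for g in genes:
        tss, cov = tissue_score(weights, graph, g) if g in graph else (None, 0.0)
        rows.append((g, interactome.tissue, tss, cov))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "tss", "coverage"])
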