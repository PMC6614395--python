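"""Target safety scores: ADR rarity, network centrality, onco-driven count.

Three complementary signals flag a gene as risky to drug:

* ADR score — ADRS(g) = -prod of freq(a) over the gene's high-level ADR
  categories. Rare categories (low frequency) pull the product toward 0,
  so a raw ADRS near 0 marks a gene linked to rare (and presumably more
  severe) adverse reactions; -1 is the safest raw value.
* centrality score — genes that are hubs of tissue-specific interactomes
  are more likely to disrupt core biology. Per tissue, genes are ranked
  by Borda-aggregated degree / weighted betweenness / weighted clustering
  (rank 1 = most connected = least safe) and the rank positions are
  summed over tissues; a gene absent from a tissue contributes that
  ranking's length + 1 (worst plus one).
* onco-driven score — the number of down-regulated oncogenic signature
  sets containing the gene; a high count suggests a tumor-suppressor-like
  profile that inhibition could derail.

For combination, each component is oriented and min-max scaled so that 1
means most unsafe, then merged with a normalized harmonic sum over the
components present for that gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import harmonic_sum, minmax_scale
from .errors import ValidationError
from .tissue import TissueInteractome, weighted_centralities, _borda_order

__all__ = [
    "AdrAnnotation",
    "category_frequencies",
    "adr_score",
    "tissue_centrality_ranking",
    "rank_position",
    "centrality_safety",
    "onco_driven_score",
    "overall_unsafety",
    "safety_table",
]


@dataclass
class AdrAnnotation:
    """Gene -> high-level ADR categories, plus each category's frequency."""

    H: dict[str, frozenset[str]]
    freq: dict[str, float]

    def __post_init__(self):
        for g, cats in self.H.items():
            missing = set(cats) - set(self.freq)
            if missing:
                raise ValidationError(
                    f"gene {g!r}: categories without a frequency: {sorted(missing)}"
                )
        for a, f in self.freq.items():
            if not (0 < f <= 1):
                raise ValidationError(f"category {a!r}: frequency {f} outside (0, 1]")

    @classmethod
    def from_annotations(cls, raw: Mapping[str, Iterable[str]]) -> "AdrAnnotation":
        h = {g: frozenset(cats) for g, cats in raw.items() if cats}
        return cls(H=h, freq=category_frequencies(h))


def category_frequencies(raw: Mapping[str, Iterable[str]]) -> dict[str, float]:
    """freq(a) = fraction of annotated genes carrying category a."""
    annotated = {g: set(cats) for g, cats in raw.items() if cats}
    if not annotated:
        raise ValidationError("no annotated genes")
    n = len(annotated)
    counts: dict[str, int] = {}
    for cats in annotated.values():
        for a in cats:
            counts[a] = counts.get(a, 0) + 1
    return {a: c / n for a, c in counts.items()}


def adr_score(gene: str, annotation: AdrAnnotation) -> float | None:
    """ADRS(g) = -prod of freq(a) over H(g); absent for unannotated genes."""
    cats = annotation.H.get(gene)
    if not cats:
        return None
    prod = 1.0
    for a in cats:
        prod *= annotation.freq[a]
    return -prod


def tissue_centrality_ranking(subnetwork: TissueInteractome) -> list[str]:
    """R(I_t): genes ordered most to least connected by Borda aggregation.

    Aggregates degree, weighted betweenness and weighted clustering ranks;
    ties broken lexicographically. Position 1 = most central = least safe.
    """
    if subnetwork.graph.number_of_nodes() == 0:
        raise ValidationError("empty tissue subnetwork")
    metrics = weighted_centralities(subnetwork)
    genes = sorted(subnetwork.graph.nodes)
    return _borda_order(genes, metrics)


def rank_position(ranking: Sequence[str], gene: str) -> int | None:
    """1-based position of a gene in a ranking; None when absent."""
    try:
        return ranking.index(gene) + 1
    except ValueError:
        return None


def centrality_safety(gene: str, rankings: Sequence[Sequence[str]]) -> float | None:
    """Sum of rank positions over tissues; absent tissues cost length + 1.

    Returns None for a gene present in no tissue ranking. Small totals mean
    high centrality everywhere, i.e. low safety.
    """
    total = 0
    seen = False
    for ranking in rankings:
        pos = rank_position(ranking, gene)
        if pos is None:
            total += len(ranking) + 1
        else:
            seen = True
            total += pos
    return float(total) if seen else None


def onco_driven_score(gene: str, sets: Sequence[Iterable[str]]) -> int:
    """Number of down-regulated oncogenic gene sets containing the gene."""
    return sum(1 for s in sets if gene in set(s))


def overall_unsafety(components: Sequence[float | None]) -> float | None:
    """Normalized harmonic sum of the oriented, scaled safety components.

    Inputs must already be scaled so 1 = most unsafe; absent components are
    skipped and the normalizer adapts to the number present.
    """
    return harmonic_sum(components, normalize=True)


def safety_table(
    genes: Iterable[str],
    annotation: AdrAnnotation | None = None,
    onco_sets: Sequence[Iterable[str]] | None = None,
    tissue_rankings: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Raw and combined safety scores for a list of genes.

    Orientation before scaling: a raw ADRS closer to 0 is more unsafe
    (min-max of ADRS already puts the most unsafe gene at 1); a smaller
    centrality total is more unsafe (scaled then flipped); a larger onco
    count is more unsafe (scaled directly). ``overall_unsafety`` is the
    normalized harmonic sum of whichever oriented components are present.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValidationError("no genes to score")
    onco_sets = [set(s) for s in (onco_sets or [])]
    rankings = list(tissue_rankings or [])
    adrs = [adr_score(g, annotation) if annotation else None for g in genes]
    cent = [centrality_safety(g, rankings) if rankings else None for g in genes]
    onco = (
        [onco_driven_score(g, onco_sets) for g in genes]
        if onco_sets
        else [None] * len(genes)
    )

    def _scaled(values, flip=False):
        arr = np.asarray(
            [np.nan if v is None else float(v) for v in values], dtype=float
        )
        if np.isnan(arr).all():
            return arr
        out = minmax_scale(arr)
        return 1.0 - out if flip else out

    adr_unsafe = _scaled(adrs)
    cent_unsafe = _scaled(cent, flip=True)
    onco_unsafe = _scaled(onco)
    overall = [
        overall_unsafety([a, c, o])
        for a, c, o in zip(adr_unsafe, cent_unsafe, onco_unsafe)
    ]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "adrs": [np.nan if v is None else v for v in adrs],
            "centrality_score": [np.nan if v is None else v for v in cent],
            "onco_score": [np.nan if v is None else v for v in onco],
            "adr_unsafe": adr_unsafe,
            "centrality_unsafe": cent_unsafe,
            "onco_unsafe": onco_unsafe,
            "overall_unsafety": [np.nan if v is None else v for v in overall],
        }
    )
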