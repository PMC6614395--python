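"""End-to-end drivers: score a synthetic world and measure recovery.

These helpers wire the scoring modules together the way the CLI does, but
in memory, so that planted-signal recovery can be measured cheaply across
many seeded worlds: modulation reverser recovery, tissue-score precision
against the planted-proximal gold standard, and safety enrichment of the
planted-unsafe genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import GoldStandard, ppv_curve, tp_rate_at_percentile
from .ensemble import add_ensemble_columns, add_ot_aggregates, minmax_scale
from .modulation import modulation_gene_scores
from .safety import AdrAnnotation, safety_table, tissue_centrality_ranking
from .synthetic import SyntheticWorld
from .tissue import build_tissue_subnetwork, score_tissue_targets

__all__ = [
    "modulation_recovery",
    "tissue_ranking",
    "tissue_normalized_ppv",
    "shuffled_gold_normalized_ppv",
    "safety_ranking",
    "safety_top_decile_precision",
    "ensemble_table",
]


def modulation_recovery(world: SyntheticWorld) -> dict[str, bool]:
    """Per disease: is the planted reverser gene the top modulation score?"""
    scores = modulation_gene_scores(
        world.disease_library, world.perturbation_library
    )
    return {
        d: scores.loc[d].idxmax() == gene
        for d, gene in world.reverser_genes.items()
    }


def tissue_ranking(
    world: SyntheticWorld, disease: str
) -> tuple[list[str], set[str]]:
    """Rank candidate genes by TSS in the disease's tissue.

    Candidates are the scored genes of the tissue subnetwork minus the
    disease genes themselves (they are the destinations, not putative
    targets); the positives are the planted-proximal genes.
    """
    tissue = world.disease_tissue[disease]
    it = next(i for i in world.interactomes() if i.tissue == tissue)
    df = score_tissue_targets(it, world.disease_genes[disease])
    df = df[~df["gene_id"].isin(world.disease_genes[disease])]
    scored = df.dropna(subset=["tss"]).sort_values(
        ["tss", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    ranked = list(scored["gene_id"])
    gold = world.proximal_positives[disease] & set(ranked)
    return ranked, gold


def _ppv_at_pct(ranked: list, gold: set, pct: float) -> float:
    depth = max(1, int(pct / 100 * len(ranked)))
    return ppv_curve(ranked, GoldStandard(gold)).at_depth(depth)


def tissue_normalized_ppv(
    world: SyntheticWorld, disease: str = "D00", pct: float = 10.0
) -> float:
    """Normalized ppv of the TSS ranking at a percentile depth."""
    ranked, gold = tissue_ranking(world, disease)
    if not gold:
        return 0.0
    return _ppv_at_pct(ranked, gold, pct)


def shuffled_gold_normalized_ppv(
    ranked: list[str],
    gold_size: int,
    rng: np.random.Generator,
    pct: float = 10.0,
    shuffles: int = 10,
) -> float:
    """Mean normalized ppv with gold labels assigned at random."""
    vals = []
    for _ in range(shuffles):
        idx = rng.choice(len(ranked), size=gold_size, replace=False)
        fake = {ranked[i] for i in idx}
        vals.append(_ppv_at_pct(ranked, fake, pct))
    return float(np.mean(vals))


def safety_ranking(
    world: SyntheticWorld, z_threshold: float = 1.0
) -> pd.DataFrame:
    """Safety table for every gene, sorted most unsafe first."""
    annotation = AdrAnnotation.from_annotations(world.adr_annotations)
    onco = [s for _, s in world.onco_sets]
    rankings = []
    for it in world.interactomes():
        sub = build_tissue_subnetwork(it, z_threshold)
        if sub.graph.number_of_nodes():
            rankings.append(tissue_centrality_ranking(sub))
    tab = safety_table(world.genes, annotation, onco, rankings)
    return tab.sort_values(
        ["overall_unsafety", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def safety_top_decile_precision(world: SyntheticWorld) -> tuple[float, float]:
    """(precision among the top unsafety decile, prevalence of planted-unsafe)."""
    tab = safety_ranking(world)
    n10 = max(1, len(tab) // 10)
    top = set(tab["gene_id"].head(n10))
    precision = len(top & world.unsafe_genes) / n10
    prevalence = len(world.unsafe_genes) / len(tab)
    return precision, prevalence


def ensemble_table(world: SyntheticWorld) -> pd.DataFrame:
    """Association table with S_m merged in and E_max / E_hs columns added."""
    scores = modulation_gene_scores(
        world.disease_library, world.perturbation_library
    )
    long = (
        scores.stack()
        .rename_axis(["disease_id", "target_id"])
        .rename("s_m")
        .reset_index()
    )
    table = world.associations.merge(long, on=["target_id", "disease_id"],
                                     how="left")
    table["s_m"] = minmax_scale(table["s_m"])
    sources = [
        c for c in world.associations.columns
        if c not in ("target_id", "disease_id")
    ]
    table = add_ot_aggregates(table, sources)
    return add_ensemble_columns(table, "s_m")
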