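"""Seeded synthetic worlds with planted signal for every scoring method.

A world emulates the statistical structure the scores assume, without any
external database:

* disease and perturbation signatures — each disease gets disjoint up/down
  gene lists; one designated "reverser" perturbation per disease overlaps
  the disease signature in opposite directions in exactly
  floor(reversal_overlap * signature_size) genes, while null perturbations
  overlap a single random disease binomially at ``null_overlap`` and fill
  the rest from genes outside every disease signature;
* a single interactome with per-tissue expression z-scores — each disease
  is assigned a tissue in which its disease genes and a handful of planted
  proximal target genes are strongly expressed, and each planted target is
  wired to several disease genes through dedicated intermediate linker
  genes (paths of ``planted_path_length`` hops). Linkers carry expression
  well above the random N(0, 1) tail and keep only their planted edges, so
  the cheap routes into the disease module are the planted ones; linkers
  are themselves proximal by construction and join the gold standard;
* safety annotations — planted-unsafe genes carry the rarest high-level
  ADR categories, appear in down-regulated oncogenic sets with elevated
  probability, and are wired as hubs that are expressed in every tissue;
* an Open-Targets-like association table whose per-source scores are noisy
  monotone transforms of the planted truth, with missing cells;
* a gold standard of (reverser gene, disease) and (proximal target,
  disease) pairs, plus truth tables recording everything planted.

All randomness flows from one ``numpy.random.Generator`` seeded by the
config, so identical configs give byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneSetLibrary, GeneSignature, write_gmt
from .tissue import TissueInteractome

__all__ = ["WorldConfig", "SyntheticWorld", "make_world", "write_fixtures"]

_SOURCES = ("genetic_association", "somatic_mutation", "literature", "rna_expression")


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults keep everything desk-scale."""

    n_genes: int = 500
    n_diseases: int = 5
    n_perturbed_genes: int = 50
    n_perturbations_per_gene: int = 3
    signature_size: int = 20
    reversal_overlap: float = 0.8
    null_overlap: float = 0.1
    n_tissues: int = 4
    edges_per_node: int = 8
    planted_path_length: int = 2
    n_disease_genes: int = 8
    n_proximal_targets: int = 5
    n_planted_destinations: int = 4
    n_hlc_categories: int = 17
    hlc_frequency_skew: float = 0.7
    n_onco_sets: int = 10
    unsafe_fraction: float = 0.1
    hub_extra_edges: int = 30
    source_missing_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_genes, self.n_diseases, self.n_perturbed_genes,
            self.n_perturbations_per_gene, self.signature_size, self.n_tissues,
            self.edges_per_node, self.planted_path_length, self.n_disease_genes,
            self.n_proximal_targets, self.n_hlc_categories, self.n_onco_sets,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all world counts must be positive")
        for name in ("reversal_overlap", "null_overlap", "unsafe_fraction",
                     "source_missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.signature_size * self.n_diseases > self.n_genes:
            raise ValidationError(
                "infeasible config: signature_size * n_diseases > n_genes"
            )
        if self.n_perturbed_genes < self.n_diseases:
            raise ValidationError("need at least one perturbed gene per disease")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    genes: list[str]
    disease_library: GeneSetLibrary
    perturbation_library: GeneSetLibrary
    edges: list[tuple[str, str]]
    expression: pd.DataFrame  # gene, tissue, z_e
    disease_genes: dict[str, set[str]]
    disease_tissue: dict[str, str]
    adr_annotations: dict[str, set[str]]
    onco_sets: list[tuple[str, set[str]]]
    associations: pd.DataFrame
    gold_pairs: set[tuple[str, str]]
    unsafe_genes: set[str]
    reverser_genes: dict[str, str]  # disease -> planted reverser gene
    reverser_perturbations: dict[str, str]  # disease -> reverser signature id
    proximal_targets: dict[str, set[str]]
    proximal_positives: dict[str, set[str]]  # targets plus planted linkers
    truth: pd.DataFrame

    def interactomes(self) -> list[TissueInteractome]:
        """Build one TissueInteractome per tissue from edges + expression."""
        base = nx.Graph()
        base.add_nodes_from(self.genes)
        base.add_edges_from(self.edges)
        out = []
        for tissue, grp in self.expression.groupby("tissue", sort=True):
            g = base.copy()
            zmap = dict(zip(grp["gene"], grp["z_e"]))
            for node in g.nodes:
                z = zmap.get(node)
                g.nodes[node]["z"] = None if z is None or math.isnan(z) else float(z)
            out.append(TissueInteractome(tissue=str(tissue), graph=g))
        return out


def _sample(rng: np.random.Generator, pool, k: int) -> list[str]:
    pool = sorted(pool)
    if k > len(pool):
        raise ValidationError(f"cannot sample {k} items from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def _make_signatures(rng, cfg, genes):
    diseases = []
    for i in range(cfg.n_diseases):
        pick = _sample(rng, genes, 2 * cfg.signature_size)
        diseases.append(
            GeneSignature(
                id=f"D{i:02d}",
                kind="disease",
                up_genes=frozenset(pick[: cfg.signature_size]),
                down_genes=frozenset(pick[cfg.signature_size:]),
            )
        )
    return diseases


def _perturbation_lists(rng, cfg, disease, neutral, k_up, k_down):
    """Down list overlapping the disease's up list in exactly k_down genes
    (and symmetrically for up), filled from the neutral pool."""
    s = cfg.signature_size
    down = set(_sample(rng, disease.up_genes, k_down))
    down |= set(_sample(rng, neutral, s - k_down))
    up = set(_sample(rng, disease.down_genes, k_up))
    up |= set(_sample(rng, set(neutral) - down, s - k_up))
    return frozenset(up), frozenset(down)


def make_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a full synthetic world from one seeded generator."""
    cfg = config or WorldConfig(**overrides)
    if config is not None and overrides:
        cfg = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- disease and perturbation signatures -----------------------------
    disease_sigs = _make_signatures(rng, cfg, genes)
    in_signatures = set().union(*[d.up_genes | d.down_genes for d in disease_sigs])
    neutral = sorted(set(genes) - in_signatures)
    if len(neutral) < 2 * cfg.signature_size:
        raise ValidationError(
            "infeasible config: not enough genes outside disease signatures"
        )
    perturbed = _sample(rng, genes, cfg.n_perturbed_genes)
    reverser_genes = {
        d.id: g for d, g in zip(disease_sigs, _sample(rng, perturbed, cfg.n_diseases))
    }
    gene_to_disease = {g: d for d, g in reverser_genes.items()}
    disease_by_id = {d.id: d for d in disease_sigs}

    pert_sigs = []
    reverser_perts: dict[str, str] = {}
    k_rev = math.floor(cfg.reversal_overlap * cfg.signature_size)
    for g in sorted(perturbed):
        for k in range(cfg.n_perturbations_per_gene):
            pid = f"{g}__p{k}"
            if k == 0 and g in gene_to_disease:
                d = disease_by_id[gene_to_disease[g]]
                up, down = _perturbation_lists(rng, cfg, d, neutral, k_rev, k_rev)
                reverser_perts[d.id] = pid
            else:
                d = disease_by_id[f"D{rng.integers(cfg.n_diseases):02d}"]
                ka = int(rng.binomial(cfg.signature_size, cfg.null_overlap))
                kb = int(rng.binomial(cfg.signature_size, cfg.null_overlap))
                up, down = _perturbation_lists(rng, cfg, d, neutral, ka, kb)
            pert_sigs.append(
                GeneSignature(
                    id=pid, kind="perturbation", up_genes=up, down_genes=down,
                    perturbed_gene=g,
                )
            )

    # --- interactome topology, unsafe hubs, planted tissue paths ---------
    base = nx.gnm_random_graph(
        cfg.n_genes, cfg.edges_per_node * cfg.n_genes,
        seed=int(rng.integers(2**31)),
    )
    base = nx.relabel_nodes(base, {i: genes[i] for i in range(cfg.n_genes)})
    base.add_nodes_from(genes)

    n_unsafe = max(1, round(cfg.unsafe_fraction * cfg.n_genes))
    unsafe = set(_sample(rng, genes, n_unsafe))
    for g in sorted(unsafe):
        for other in _sample(rng, set(genes) - {g}, cfg.hub_extra_edges):
            base.add_edge(g, other)

    tissues = [f"T{t:02d}" for t in range(cfg.n_tissues)]
    disease_tissue = {
        d.id: tissues[i % cfg.n_tissues] for i, d in enumerate(disease_sigs)
    }
    z = {t: dict(zip(genes, rng.normal(0.0, 1.0, cfg.n_genes))) for t in tissues}
    for t in tissues:  # unsafe hubs expressed (but not cheap conduits) everywhere
        for g in sorted(unsafe):
            z[t][g] = float(rng.uniform(1.2, 1.8))

    disease_genes: dict[str, set[str]] = {}
    proximal: dict[str, set[str]] = {}
    intermediates_used: dict[str, set[str]] = {}
    reserved = set(unsafe)
    for d in disease_sigs:
        t = disease_tissue[d.id]
        d_genes = set(_sample(rng, set(genes) - reserved, cfg.n_disease_genes))
        reserved |= d_genes
        targets = set(_sample(rng, set(genes) - reserved, cfg.n_proximal_targets))
        reserved |= targets
        disease_genes[d.id] = d_genes
        proximal[d.id] = targets
        inters: set[str] = set()
        for g in sorted(d_genes | targets):
            z[t][g] = float(rng.uniform(1.5, 3.0))
        n_dest = min(cfg.n_planted_destinations, cfg.n_disease_genes)
        for tau in sorted(targets):
            prev = tau
            for _ in range(cfg.planted_path_length - 1):
                inter = _sample(rng, set(genes) - reserved, 1)[0]
                reserved.add(inter)
                inters.add(inter)
                # dedicated linker: planted edges only, expression above
                # the random tail so the cheap route is the planted one
                base.remove_edges_from(list(base.edges(inter)))
                z[t][inter] = float(rng.uniform(3.5, 4.0))
                base.add_edge(prev, inter)
                prev = inter
            for dest in _sample(rng, d_genes, n_dest):
                base.add_edge(prev, dest)
        intermediates_used[d.id] = inters

    edges = sorted(tuple(sorted(e)) for e in base.edges)
    expression = pd.DataFrame(
        [(g, t, z[t][g]) for t in tissues for g in genes],
        columns=["gene", "tissue", "z_e"],
    )

    # --- ADR and onco annotations ----------------------------------------
    hlcs = [f"HLC{i:02d}" for i in range(cfg.n_hlc_categories)]
    assign_p = cfg.hlc_frequency_skew ** np.arange(cfg.n_hlc_categories)
    assign_p /= assign_p.sum()
    rare = hlcs[-max(3, cfg.n_hlc_categories // 3):]
    n_annotated = max(n_unsafe, round(0.4 * cfg.n_genes))
    annotated = set(unsafe) | set(
        _sample(rng, set(genes) - unsafe, max(0, n_annotated - n_unsafe))
    )
    adr: dict[str, set[str]] = {}
    for g in sorted(annotated):
        if g in unsafe:
            k = int(rng.integers(1, 3))
            adr[g] = set(_sample(rng, rare, k))
        else:
            k = int(rng.integers(1, 4))
            cats = rng.choice(cfg.n_hlc_categories, size=k, replace=False, p=assign_p)
            adr[g] = {hlcs[i] for i in cats}

    onco_sets: list[tuple[str, set[str]]] = []
    for s in range(cfg.n_onco_sets):
        members = {
            g
            for g in genes
            if rng.random() < (0.5 if g in unsafe else 0.02)
        }
        if not members:
            members = set(_sample(rng, unsafe, 1))
        onco_sets.append((f"ONCO{s:02d}_DN", members))

    # --- gold standard and OT-like association table ----------------------
    proximal_positives = {
        d.id: proximal[d.id] | intermediates_used[d.id] for d in disease_sigs
    }
    gold = {(reverser_genes[d.id], d.id) for d in disease_sigs}
    for d in disease_sigs:
        gold |= {(g, d.id) for g in proximal_positives[d.id]}
    candidates = sorted(
        set(perturbed) | set().union(*proximal.values())
    )
    rows = []
    for g in candidates:
        for d in disease_sigs:
            rel = (g, d.id) in gold
            scores = {}
            for src in _SOURCES:
                if rng.random() < cfg.source_missing_rate:
                    scores[src] = np.nan
                else:
                    lo, hi = (0.5, 1.0) if rel else (0.0, 0.5)
                    scores[src] = float(rng.uniform(lo, hi))
            rows.append({"target_id": g, "disease_id": d.id, **scores})
    associations = pd.DataFrame(rows)

    truth_rows = []
    for d in disease_sigs:
        truth_rows.append(("reverser_gene", d.id, reverser_genes[d.id]))
        truth_rows.append(("reverser_perturbation", d.id, reverser_perts[d.id]))
        truth_rows += [("disease_gene", d.id, g) for g in sorted(disease_genes[d.id])]
        truth_rows += [("proximal_target", d.id, g) for g in sorted(proximal[d.id])]
        truth_rows += [
            ("planted_intermediate", d.id, g)
            for g in sorted(intermediates_used[d.id])
        ]
    truth_rows += [("unsafe_gene", "", g) for g in sorted(unsafe)]
    truth = pd.DataFrame(truth_rows, columns=["kind", "disease_id", "id"])

    return SyntheticWorld(
        config=cfg,
        genes=genes,
        disease_library=GeneSetLibrary(entries=disease_sigs),
        perturbation_library=GeneSetLibrary(entries=pert_sigs),
        edges=edges,
        expression=expression,
        disease_genes=disease_genes,
        disease_tissue=disease_tissue,
        adr_annotations=adr,
        onco_sets=onco_sets,
        associations=associations,
        gold_pairs=gold,
        unsafe_genes=unsafe,
        reverser_genes=reverser_genes,
        reverser_perturbations=reverser_perts,
        proximal_targets=proximal,
        proximal_positives=proximal_positives,
        truth=truth,
    )


def write_fixtures(
    world: SyntheticWorld, directory: str | Path, force: bool = False
) -> dict:
    """Write every fixture file and return a manifest (config + checksums)."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ValidationError(
            f"{directory} is not empty; pass force=True to overwrite"
        )
    directory.mkdir(parents=True, exist_ok=True)

    write_gmt(world.disease_library, directory / "diseases.gmt")
    write_gmt(world.perturbation_library, directory / "perturbations.gmt")
    pd.DataFrame(world.edges, columns=["gene_a", "gene_b"]).to_csv(
        directory / "edges.tsv", sep="\t", index=False
    )
    world.expression.to_csv(
        directory / "expression.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        [(d, g) for d in sorted(world.disease_genes) for g in
         sorted(world.disease_genes[d])],
        columns=["disease_id", "gene_id"],
    ).to_csv(directory / "disease_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(world.disease_tissue.items()), columns=["disease_id", "tissue"]
    ).to_csv(directory / "disease_tissues.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, a) for g in sorted(world.adr_annotations)
         for a in sorted(world.adr_annotations[g])],
        columns=["gene_id", "hlc"],
    ).to_csv(directory / "adr.tsv", sep="\t", index=False)
    with (directory / "onco_dn.gmt").open("w") as fh:
        for name, members in world.onco_sets:
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")
    world.associations.to_csv(
        directory / "associations.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        sorted(world.gold_pairs), columns=["target_id", "disease_id"]
    ).to_csv(directory / "gold_standard.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, "planted") for g in sorted(world.unsafe_genes)],
        columns=["target_id", "category"],
    ).to_csv(directory / "unsafe_targets.tsv", sep="\t", index=False)
    world.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)

    files = sorted(p.name for p in directory.iterdir() if p.name != "manifest.json")
    checksums = {
        name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
        for name in files
    }
    manifest = {
        "config": dataclasses.asdict(world.config),
        "files": checksums,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
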