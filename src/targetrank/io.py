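"""File formats: GMT gene-set libraries, interactome TSVs, score tables.

All tabular formats are TSV with a header row. Gene and disease identifiers
are opaque strings — no ontology resolution happens here. Empty numeric
cells read back as absent (NaN), never as zero.

GMT direction encoding: signature names ending in ``_up`` / ``_down``
(case-insensitive) are paired into a single up/down signature under the
stripped base name; a name without a direction suffix is taken as an
up-regulated list. For perturbation libraries the GMT description field
carries the perturbed gene; when it is empty or ".", the id prefix before
the first ``__`` is used.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .tissue import TissueInteractome

__all__ = [
    "GeneSignature",
    "GeneSetLibrary",
    "RunConfig",
    "read_gmt",
    "write_gmt",
    "read_network",
    "read_association_table",
    "write_association_table",
    "read_gold_standard",
    "read_unsafe_targets",
    "read_adr_annotations",
    "read_disease_genes",
]


@dataclass(frozen=True)
class GeneSignature:
    """An up/down-regulated gene list attached to a disease or perturbation."""

    id: str
    kind: str  # "disease" or "perturbation"
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    perturbed_gene: str | None = None

    def __post_init__(self):
        if self.kind not in ("disease", "perturbation"):
            raise ValidationError(f"unknown signature kind {self.kind!r}")
        if self.up_genes & self.down_genes:
            overlap = sorted(self.up_genes & self.down_genes)[:5]
            raise ValidationError(
                f"signature {self.id!r}: genes in both up and down lists: {overlap}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValidationError(f"signature {self.id!r}: both gene lists empty")
        if self.kind == "perturbation" and not self.perturbed_gene:
            raise ValidationError(
                f"signature {self.id!r}: perturbation without a perturbed gene"
            )


@dataclass
class GeneSetLibrary:
    entries: list[GeneSignature]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate signature ids: {dupes[:5]}")
        if not self.universe:
            self.universe = set().union(
                *[e.up_genes | e.down_genes for e in self.entries], set()
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def perturbation_map(self) -> dict[str, set[str]]:
        """P_g: gene -> the set of its perturbation signature ids."""
        p_g: dict[str, set[str]] = {}
        for e in self.entries:
            if e.kind == "perturbation":
                p_g.setdefault(e.perturbed_gene, set()).add(e.id)
        return p_g


_UP_SUFFIX = "_up"
_DOWN_SUFFIX = "_down"


def _split_direction(name: str) -> tuple[str, str]:
    low = name.lower()
    if low.endswith(_UP_SUFFIX):
        return name[: -len(_UP_SUFFIX)], "up"
    if low.endswith(_DOWN_SUFFIX):
        return name[: -len(_DOWN_SUFFIX)], "down"
    return name, "up"


def _perturbed_gene(base_id: str, description: str) -> str:
    if description and description != ".":
        return description
    return base_id.split("__")[0]


def read_gmt(path: str | Path, kind: str = "disease") -> GeneSetLibrary:
    """Parse a GMT file into a library, pairing _up/_down lines by base name."""
    path = Path(path)
    partial: dict[str, dict] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            base, direction = _split_direction(name)
            if base not in partial:
                partial[base] = {"up": frozenset(), "down": frozenset(),
                                 "description": description}
                order.append(base)
            partial[base][direction] = partial[base][direction] | genes
    entries = []
    for base in order:
        rec = partial[base]
        entries.append(
            GeneSignature(
                id=base,
                kind=kind,
                up_genes=rec["up"],
                down_genes=rec["down"],
                perturbed_gene=(
                    _perturbed_gene(base, rec["description"])
                    if kind == "perturbation"
                    else None
                ),
            )
        )
    return GeneSetLibrary(entries=entries)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library as GMT, one _up and one _down line per signature."""
    path = Path(path)
    with path.open("w") as fh:
        for sig in library.entries:
            desc = sig.perturbed_gene if sig.kind == "perturbation" else "."
            for suffix, genes in (("_up", sig.up_genes), ("_down", sig.down_genes)):
                if genes:
                    fh.write(
                        "\t".join([sig.id + suffix, desc or "."] + sorted(genes))
                        + "\n"
                    )


def read_network(
    edges_path: str | Path, expression_path: str | Path
) -> list[TissueInteractome]:
    """Load one interactome plus per-tissue expression into tissue graphs.

    Returns one :class:`TissueInteractome` per tissue in the expression
    table, all sharing the edge topology. Self-loops are dropped and
    duplicate undirected edges collapsed; genes without an expression value
    in a tissue carry an absent z_E.
    """
    import networkx as nx

    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in edges.columns:
            raise ParseError(f"{edges_path}: missing column {col!r}")
    if len(edges) == 0:
        raise ValidationError(f"{edges_path}: empty edge list")
    expr = pd.read_csv(expression_path, sep="\t", dtype={"gene": str, "tissue": str})
    for col in ("gene", "tissue", "z_e"):
        if col not in expr.columns:
            raise ParseError(f"{expression_path}: missing column {col!r}")
    z_numeric = pd.to_numeric(expr["z_e"], errors="coerce")
    bad = expr["z_e"].notna() & z_numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ParseError(f"{expression_path}: non-numeric z_e at line {row}")
    expr["z_e"] = z_numeric

    base = nx.Graph()
    for a, b in edges[["gene_a", "gene_b"]].itertuples(index=False):
        if a == b:
            continue  # self-loop
        base.add_edge(a, b)
    interactomes = []
    for tissue, grp in expr.groupby("tissue", sort=True):
        g = base.copy()
        zmap = dict(zip(grp["gene"], grp["z_e"]))
        for node in g.nodes:
            z = zmap.get(node)
            g.nodes[node]["z"] = float(z) if z is not None and not math.isnan(z) else None
        interactomes.append(TissueInteractome(tissue=str(tissue), graph=g))
    return interactomes


def read_association_table(path: str | Path) -> pd.DataFrame:
    """Read a target-disease association score table.

    Columns: target_id, disease_id, then one or more numeric score columns
    in [0, 1]. Empty cells become NaN (absent), which aggregations skip.
    """
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "disease_id": str})
    for col in ("target_id", "disease_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    score_cols = [c for c in df.columns if c not in ("target_id", "disease_id")]
    if not score_cols:
        raise ParseError(f"{path}: no score columns")
    for c in score_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        bad = df[c].dropna()
        outside = bad[(bad < 0) | (bad > 1)]
        if len(outside):
            raise ValidationError(
                f"{path}: column {c!r} has scores outside [0,1] at rows "
                f"{list(outside.index[:5])}"
            )
    if df.duplicated(["target_id", "disease_id"]).any():
        raise ValidationError(f"{path}: duplicate (target, disease) rows")
    return df


def write_association_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gold_standard(path: str | Path) -> set:
    """Gold-standard positives: (target_id, disease_id) pairs, or targets only."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "target_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'target_id'")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty gold standard")
    if "disease_id" in df.columns:
        return set(zip(df["target_id"], df["disease_id"]))
    return set(df["target_id"])


def read_unsafe_targets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("target_id",):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def read_adr_annotations(path: str | Path) -> dict[str, set[str]]:
    """Gene -> set of high-level ADR categories, from a (gene_id, hlc) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "hlc"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ann: dict[str, set[str]] = {}
    for g, h in zip(df["gene_id"], df["hlc"]):
        ann.setdefault(g, set()).add(h)
    return ann


def read_disease_genes(path: str | Path) -> dict[str, set[str]]:
    """Disease -> set of known disease genes, from a (disease_id, gene_id) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("disease_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out: dict[str, set[str]] = {}
    for d, g in zip(df["disease_id"], df["gene_id"]):
        out.setdefault(d, set()).add(g)
    return out


@dataclass
class RunConfig:
    """Pipeline parameters; YAML-configurable, every CLI flag overrides."""

    seed: int = 0
    z_threshold: float = 1.0
    w_efficacy: float = 0.5
    w_safety: float = 0.5
    bootstrap_reps: int = 100
    bootstrap_frac: float = 0.8
    percentiles: tuple[float, ...] = (1.0, 5.0, 10.0)

    def __post_init__(self):
        if not (0 < self.bootstrap_frac <= 1):
            raise ValidationError("bootstrap_frac must lie in (0, 1]")
        if any(not (0 < p <= 100) for p in self.percentiles):
            raise ValidationError("percentiles must lie in (0, 100]")
        if abs(self.w_efficacy + self.w_safety - 1.0) > 1e-9:
            raise ValidationError("w_efficacy + w_safety must equal 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "percentiles" in data:
            data["percentiles"] = tuple(float(p) for p in data["percentiles"])
        return cls(**data)
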