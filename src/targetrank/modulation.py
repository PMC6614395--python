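"""Modulation efficacy score: does perturbing a gene reverse a disease signature?

Two co-occurrence matrices are built over all (disease, perturbation)
pairs: C' counts genes up in the disease and down in the perturbation,
C'' the reverse. A cell is scored against its background by a composite
z-score f(Z_i, Z_j) = Z_i + Z_j, where Z_i standardizes the cell against
its row (all perturbations for that disease) and Z_j against its column
(all diseases for that perturbation); standard deviations are population
(N-denominator), and a zero-variance background contributes Z = 0 — a
cell indistinguishable from a constant background carries no evidence.

MS(i, j) = (f' + f'') / 2 averaged over the two matrices; per gene,
MS(i, g) keeps the best-scoring of the gene's perturbations. Scores can
be negative (anti-reversal); scaling to [0, 1] happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneSetLibrary

__all__ = [
    "CooccurrenceMatrices",
    "count_cooccurrence",
    "build_cooccurrence",
    "composite_zscore",
    "modulation_pair_scores",
    "collapse_to_genes",
    "modulation_gene_scores",
]


def count_cooccurrence(set_a: set, set_b: set) -> int:
    """Number of shared genes between two gene sets."""
    return len(set(set_a) & set(set_b))


@dataclass
class CooccurrenceMatrices:
    """Reversal co-occurrence counts for diseases x perturbations.

    ``c_up_down[i, j]`` = |up(disease i) ∩ down(perturbation j)| and
    ``c_down_up[i, j]`` = |down(disease i) ∩ up(perturbation j)|.
    """

    diseases: list[str]
    perturbations: list[str]
    c_up_down: np.ndarray
    c_down_up: np.ndarray

    def __post_init__(self):
        shape = (len(self.diseases), len(self.perturbations))
        for name in ("c_up_down", "c_down_up"):
            m = np.asarray(getattr(self, name))
            if m.shape != shape:
                raise ValidationError(f"{name} has shape {m.shape}, expected {shape}")
            if (m < 0).any():
                raise ValidationError(f"{name} has negative counts")
            setattr(self, name, m.astype(float))


def build_cooccurrence(
    diseases: GeneSetLibrary, perturbations: GeneSetLibrary
) -> CooccurrenceMatrices:
    """Count reversed genes for every (disease, perturbation) pair."""
    if len(diseases) == 0 or len(perturbations) == 0:
        raise ValidationError("both libraries must be non-empty")
    d_ids = [e.id for e in diseases]
    p_ids = [e.id for e in perturbations]
    c_ud = np.zeros((len(d_ids), len(p_ids)))
    c_du = np.zeros_like(c_ud)
    for i, d in enumerate(diseases):
        for j, p in enumerate(perturbations):
            c_ud[i, j] = count_cooccurrence(d.up_genes, p.down_genes)
            c_du[i, j] = count_cooccurrence(d.down_genes, p.up_genes)
    return CooccurrenceMatrices(
        diseases=d_ids, perturbations=p_ids, c_up_down=c_ud, c_down_up=c_du
    )


def _composite_matrix(m: np.ndarray) -> np.ndarray:
    """f(Z_i, Z_j) for every cell: row z-score plus column z-score."""
    row_mean = m.mean(axis=1, keepdims=True)
    row_sd = m.std(axis=1, keepdims=True)  # population sd
    col_mean = m.mean(axis=0, keepdims=True)
    col_sd = m.std(axis=0, keepdims=True)
    z_row = np.where(row_sd == 0, 0.0, (m - row_mean) / np.where(row_sd == 0, 1, row_sd))
    z_col = np.where(col_sd == 0, 0.0, (m - col_mean) / np.where(col_sd == 0, 1, col_sd))
    return z_row + z_col


def composite_zscore(matrix: np.ndarray, i: int, j: int) -> float:
    """f(Z_i, Z_j) for one cell of a co-occurrence matrix.

    Requires at least a 2x2 matrix so the row and column backgrounds are
    non-degenerate.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("matrix must have at least 2 rows and 2 columns")
    return float(_composite_matrix(m)[i, j])


def modulation_pair_scores(cm: CooccurrenceMatrices) -> pd.DataFrame:
    """MS(i, j) for every pair, as a diseases x perturbations DataFrame."""
    for m in (cm.c_up_down, cm.c_down_up):
        if m.shape[0] < 2 or m.shape[1] < 2:
            raise ValidationError(
                "need >=2 diseases and >=2 perturbations for a background"
            )
    ms = 0.5 * (_composite_matrix(cm.c_up_down) + _composite_matrix(cm.c_down_up))
    return pd.DataFrame(ms, index=cm.diseases, columns=cm.perturbations)


def collapse_to_genes(
    pair_scores: pd.DataFrame, p_g: Mapping[str, set]
) -> pd.DataFrame:
    """MS(i, g) = max over MS(i, a) for the gene's perturbations a in P_g.

    Genes absent from ``p_g`` get no score; every referenced perturbation
    must have a column in ``pair_scores``.
    """
    known = set(pair_scores.columns)
    for gene, perts in p_g.items():
        unknown = set(perts) - known
        if unknown:
            raise ValidationError(
                f"gene {gene!r} references unknown perturbations: {sorted(unknown)[:5]}"
            )
        if not perts:
            raise ValidationError(f"gene {gene!r} has an empty perturbation set")
    cols = {
        gene: pair_scores[sorted(perts)].max(axis=1)
        for gene, perts in sorted(p_g.items())
    }
    return pd.DataFrame(cols, index=pair_scores.index)


def modulation_gene_scores(
    diseases: GeneSetLibrary, perturbations: GeneSetLibrary
) -> pd.DataFrame:
    """End-to-end MS(i, g): co-occurrence, pair scores, per-gene collapse."""
    cm = build_cooccurrence(diseases, perturbations)
    pairs = modulation_pair_scores(cm)
    return collapse_to_genes(pairs, perturbations.perturbation_map())
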