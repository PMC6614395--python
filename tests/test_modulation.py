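import numpy as np
import pandas as pd
import pytest

from targetrank.errors import ValidationError
from targetrank.io import GeneSetLibrary, GeneSignature
from targetrank.modulation import (
    CooccurrenceMatrices,
    build_cooccurrence,
    collapse_to_genes,
    composite_zscore,
    count_cooccurrence,
    modulation_pair_scores,
)


def _lib(kind, sigs):
    entries = [
        GeneSignature(
            id=i, kind=kind, up_genes=frozenset(u), down_genes=frozenset(d),
            perturbed_gene=i.split("__")[0] if kind == "perturbation" else None,
        )
        for i, u, d in sigs
    ]
    return GeneSetLibrary(entries=entries)


def _random_library(rng, kind, n_sigs, universe):
    sigs = []
    for i in range(n_sigs):
        genes = rng.choice(universe, size=rng.integers(4, 10), replace=False)
        cut = rng.integers(1, len(genes))
        sigs.append((f"{kind[0]}{i}__x", set(genes[:cut]), set(genes[cut:])))
    return _lib(kind, sigs)


def brute_force_ms(diseases, perturbations):
    """Independent recomputation of MS(i,j) from raw set intersections."""

    def zcell(mat, i, j):
        row, col = mat[i, :], mat[:, j]
        z = 0.0
        for vec in (row, col):
            mu = sum(vec) / len(vec)
            sd = (sum((v - mu) ** 2 for v in vec) / len(vec)) ** 0.5
            z += 0.0 if sd == 0 else (mat[i, j] - mu) / sd
        return z

    d, p = list(diseases), list(perturbations)
    c1 = np.array([[len(di.up_genes & pj.down_genes) for pj in p] for di in d],
                  dtype=float)
    c2 = np.array([[len(di.down_genes & pj.up_genes) for pj in p] for di in d],
                  dtype=float)
    return np.array(
        [[0.5 * (zcell(c1, i, j) + zcell(c2, i, j)) for j in range(len(p))]
         for i in range(len(d))]
    )


def test_count_cooccurrence_is_intersection_size():
    assert count_cooccurrence({"A", "B", "C"}, {"B", "C", "D"}) == 2
    assert count_cooccurrence({"A"}, set()) == 0
    assert count_cooccurrence({"A", "B"}, {"A", "B"}) == 2


def test_build_cooccurrence_counts_reversed_genes_per_direction():
    d = _lib("disease", [("d1", {"A", "B"}, {"C"}), ("d2", {"X"}, {"Y"})])
    p = _lib("perturbation", [("p1__x", {"C"}, {"A"}), ("p2__x", {"Q"}, {"R"})])
    cm = build_cooccurrence(d, p)
    assert cm.c_up_down[0, 0] == 1  # up {A,B} vs down {A}
    assert cm.c_down_up[0, 0] == 1  # down {C} vs up {C}
    assert cm.c_up_down[1, 1] == 0 and cm.c_down_up[1, 1] == 0


def test_build_cooccurrence_rejects_empty_library():
    d = _lib("disease", [("d1", {"A"}, {"B"})])
    with pytest.raises(ValidationError):
        build_cooccurrence(d, GeneSetLibrary(entries=[]))


def test_composite_zscore_hand_example():
    # row [0,2,4] at cell value 4; column [4,1,1]: population-sd z-scores
    m = np.array([[0.0, 2.0, 4.0], [9.0, 1.0, 1.0], [9.0, 9.0, 1.0]])
    z = composite_zscore(m, 0, 2)
    assert z == pytest.approx(2.0 / 1.6329932 + 2.0 / 1.4142136, abs=1e-5)
    assert z == pytest.approx(2.63896, abs=1e-5)


def test_composite_zscore_zero_variance_background_contributes_zero():
    m = np.array([[1.0, 3.0, 5.0], [0.0, 3.0, 9.0], [2.0, 3.0, 4.0]])
    # column 1 is constant -> Z_j = 0; row value 3 is the row mean -> Z_i = 0
    assert composite_zscore(m, 0, 1) == 0.0
    assert composite_zscore(np.full((3, 3), 7.0), 1, 1) == 0.0


def test_composite_zscore_rejects_degenerate_background():
    with pytest.raises(ValidationError):
        composite_zscore(np.array([[1.0, 2.0]]), 0, 0)


def test_pair_scores_average_the_two_matrices():
    cm = CooccurrenceMatrices(
        diseases=["d1", "d2"],
        perturbations=["p1", "p2"],
        c_up_down=np.array([[2, 0], [0, 2]]),
        c_down_up=np.array([[1, 1], [1, 1]]),
    )
    ms = modulation_pair_scores(cm)
    f1 = composite_zscore(cm.c_up_down, 0, 0)
    f2 = composite_zscore(cm.c_down_up, 0, 0)
    assert ms.loc["d1", "p1"] == pytest.approx(0.5 * (f1 + f2))
    # constant matrix contributes 0 everywhere
    assert ms.loc["d1", "p2"] == pytest.approx(0.5 * composite_zscore(cm.c_up_down, 0, 1))


@pytest.mark.parametrize("seed", range(5))
def test_pair_scores_match_bruteforce_on_random_libraries(seed):
    rng = np.random.default_rng(seed)
    universe = [f"G{i}" for i in range(50)]
    d = _random_library(rng, "disease", 6, universe)
    p = _random_library(rng, "perturbation", 7, universe)
    ms = modulation_pair_scores(build_cooccurrence(d, p))
    expected = brute_force_ms(d, p)
    np.testing.assert_allclose(ms.to_numpy(), expected, atol=1e-12)


def test_permutation_equivariance():
    rng = np.random.default_rng(42)
    universe = [f"G{i}" for i in range(30)]
    d = _random_library(rng, "disease", 5, universe)
    p = _random_library(rng, "perturbation", 6, universe)
    ms = modulation_pair_scores(build_cooccurrence(d, p))
    d_perm = GeneSetLibrary(entries=[d.entries[i] for i in (3, 0, 4, 1, 2)])
    ms_perm = modulation_pair_scores(build_cooccurrence(d_perm, p))
    pd.testing.assert_frame_equal(ms_perm, ms.reindex(ms_perm.index))


def test_shift_invariance_of_scores():
    # adding a constant to every cell of both matrices leaves MS unchanged
    rng = np.random.default_rng(0)
    c1 = rng.integers(0, 6, size=(4, 5)).astype(float)
    c2 = rng.integers(0, 6, size=(4, 5)).astype(float)
    ids = [f"d{i}" for i in range(4)], [f"p{j}" for j in range(5)]
    ms = modulation_pair_scores(CooccurrenceMatrices(*ids, c1, c2))
    ms_shift = modulation_pair_scores(CooccurrenceMatrices(*ids, c1 + 3, c2 + 3))
    np.testing.assert_allclose(ms.to_numpy(), ms_shift.to_numpy(), atol=1e-12)


class TestCollapseToGenes:
    def test_takes_maximum_over_a_genes_perturbations(self):
        pairs = pd.DataFrame(
            [[0.2, 1.7, -0.5]], index=["d1"], columns=["a1", "a2", "a3"]
        )
        out = collapse_to_genes(pairs, {"g": {"a1", "a2", "a3"}, "h": {"a3"}})
        assert out.loc["d1", "g"] == 1.7
        assert out.loc["d1", "h"] == -0.5  # single perturbation -> identity

    def test_unknown_perturbation_rejected(self):
        pairs = pd.DataFrame([[0.1]], index=["d1"], columns=["a1"])
        with pytest.raises(ValidationError):
            collapse_to_genes(pairs, {"g": {"a1", "zzz"}})
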