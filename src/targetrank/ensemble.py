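"""Score scaling, evidence aggregation and efficacy/safety prioritization.

Per-source association scores (Open-Targets-like columns plus the two
transcriptome-based scores) are combined in two ways:

* ``e_max`` — the maximum of the per-source maximum and a new score;
* ``e_hs`` — the maximum of the harmonic sum of the per-source scores
  and a new score.

The harmonic sum sorts scores descending and weights them 1, 1/2, 1/4, ...;
normalization divides by the maximum attainable sum for the number of
scores present, which maps the result back to [0, 1].

Missing scores are genuinely absent (NaN), never zero: a target with no
evidence from a source is distinguishable from a target scored zero by it.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "minmax_scale",
    "harmonic_sum",
    "e_max",
    "e_hs",
    "add_ot_aggregates",
    "add_ensemble_columns",
    "prioritize",
]


def _is_absent(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def minmax_scale(values: Iterable[float]) -> np.ndarray:
    """Scale values to [0, 1] by (v - min) / (max - min).

    Absent values (NaN) pass through untouched and do not influence the
    range. A constant vector maps to all 0.5 — a flat score carries no
    ranking information, so every item sits mid-scale.
    """
    arr = np.asarray(
        [np.nan if _is_absent(v) else float(v) for v in values], dtype=float
    )
    if arr.size == 0:
        raise ValidationError("minmax_scale: empty input")
    present = ~np.isnan(arr)
    if not present.any():
        raise ValidationError("minmax_scale: all values absent")
    lo = arr[present].min()
    hi = arr[present].max()
    out = np.full(arr.shape, np.nan)
    if hi == lo:
        out[present] = 0.5
    else:
        out[present] = (arr[present] - lo) / (hi - lo)
    return out


def harmonic_sum(scores: Iterable[float], normalize: bool = False) -> float | None:
    """Harmonic sum of scores in [0, 1]; absent entries are skipped.

    Scores are sorted descending as s(1) >= s(2) >= ... and combined as
    sum_k s(k) / 2**(k-1). With ``normalize`` the sum is divided by
    sum_k 1 / 2**(k-1) over the number of present scores, so a vector of
    all ones maps to exactly 1. Returns None when every score is absent.
    """
    vals = [float(v) for v in scores if not _is_absent(v)]
    if not vals:
        return None
    arr = np.asarray(vals)
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("harmonic_sum: scores must lie in [0, 1]")
    arr = np.sort(arr)[::-1]
    w = 0.5 ** np.arange(arr.size)
    raw = float(arr @ w)
    if not normalize:
        return raw
    return raw / float(w.sum())


def e_max(ot_scores: Sequence[float], s_new: float | None) -> float | None:
    """max(max over present OT scores, new score); None if nothing present."""
    vals = [float(v) for v in ot_scores if not _is_absent(v)]
    if not _is_absent(s_new):
        vals.append(float(s_new))
    if not vals:
        return None
    return max(vals)


def e_hs(ot_hs: float | None, s_new: float | None) -> float | None:
    """max of the OT harmonic sum and a new score, over present values."""
    vals = [float(v) for v in (ot_hs, s_new) if not _is_absent(v)]
    if not vals:
        return None
    return max(vals)


def add_ot_aggregates(
    table: pd.DataFrame,
    source_cols: Sequence[str],
    exclude: Sequence[str] = (),
    normalize: bool = True,
) -> pd.DataFrame:
    """Add ``ot_max`` and ``ot_hs`` columns aggregating per-source scores.

    ``exclude`` drops evidence sources before aggregation (e.g. known-drug
    evidence, which would leak the gold standard into the ranking).
    """
    cols = [c for c in source_cols if c not in set(exclude)]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"unknown source columns: {missing}")
    if not cols:
        raise ValidationError("no source columns left after exclusion")
    out = table.copy()
    sub = out[cols]
    out["ot_max"] = sub.max(axis=1, skipna=True)
    out["ot_hs"] = [
        hs if (hs := harmonic_sum(row, normalize=normalize)) is not None else np.nan
        for row in sub.to_numpy()
    ]
    return out


def add_ensemble_columns(table: pd.DataFrame, new_score_col: str) -> pd.DataFrame:
    """Add ``e_max`` and ``e_hs`` columns combining OT aggregates with a new score.

    Requires ``ot_max`` and ``ot_hs`` (see :func:`add_ot_aggregates`); rows
    where every input is absent get absent ensembles.
    """
    for c in ("ot_max", "ot_hs", new_score_col):
        if c not in table.columns:
            raise ValidationError(f"column {c!r} missing from table")
    out = table.copy()
    out["e_max"] = [
        v if (v := e_max([om], sn)) is not None else np.nan
        for om, sn in zip(out["ot_max"], out[new_score_col])
    ]
    out["e_hs"] = [
        v if (v := e_hs(oh, sn)) is not None else np.nan
        for oh, sn in zip(out["ot_hs"], out[new_score_col])
    ]
    return out


def prioritize(
    table: pd.DataFrame,
    w_efficacy: float = 0.5,
    w_safety: float = 0.5,
) -> pd.DataFrame:
    """Weighted efficacy/safety ranking of target-disease pairs.

    ``table`` needs columns target_id, disease_id, efficacy, unsafety (all
    scores already in [0, 1]). safety = 1 - unsafety and
    overall = w_e * efficacy + w_s * safety. Rows are sorted by overall
    descending, ties broken by efficacy then target id so the ranking is
    reproducible.
    """
    if w_efficacy < 0 or w_safety < 0:
        raise ValidationError("weights must be non-negative")
    if abs(w_efficacy + w_safety - 1.0) > 1e-9:
        raise ValidationError("w_efficacy + w_safety must equal 1")
    for c in ("target_id", "disease_id", "efficacy", "unsafety"):
        if c not in table.columns:
            raise ValidationError(f"column {c!r} missing from table")
    for c in ("efficacy", "unsafety"):
        vals = table[c].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{c} values must lie in [0, 1]")
    out = table.copy()
    out["safety"] = 1.0 - out["unsafety"]
    out["overall"] = w_efficacy * out["efficacy"] + w_safety * out["safety"]
    out = out.sort_values(
        ["overall", "efficacy", "target_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out[["target_id", "disease_id", "efficacy", "safety", "overall"]]
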