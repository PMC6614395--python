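"""Benchmarking rankings against gold standards.

Rankings of target-disease pairs (or bare targets, for safety) are judged
by precision among the top k — the positive predictive value — normalized
by the precision a random ordering would achieve (the prevalence of
positives in the ranked universe). A normalized ppv of 1 is chance level;
x means x-fold better than random. True-positive rates are reported at the
1st/5th/10th percentile depths of the ranking, with uncertainty from
resampling a fraction of the gold standard, and methods are compared with
a one-way ANOVA followed by Tukey's HSD on the replicate TP rates.

The F statistic and the studentized-range q are computed from their sums
of squares directly; scipy supplies the reference distributions and
statsmodels the Benjamini-Hochberg adjustment across pairs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "GoldStandard",
    "PpvCurve",
    "BootstrapSummary",
    "ppv_curve",
    "tp_rate_at_percentile",
    "bootstrap_tp",
    "compare_methods",
    "benchmark_report",
    "write_report",
]


@dataclass
class GoldStandard:
    """Known positives: (target, disease) pairs or target ids."""

    positives: set
    label: str = "gold"

    def __post_init__(self):
        if not self.positives:
            raise ValidationError("empty gold standard")


@dataclass
class PpvCurve:
    ks: np.ndarray
    ppv: np.ndarray
    normalized_ppv: np.ndarray
    prevalence: float

    def at_depth(self, k: int) -> float:
        idx = int(np.searchsorted(self.ks, k))
        if idx >= len(self.ks) or self.ks[idx] != k:
            raise ValidationError(f"depth {k} not on curve")
        return float(self.normalized_ppv[idx])


def ppv_curve(
    ranked: Sequence[Hashable],
    gold: GoldStandard,
    max_depth_fraction: float = 0.5,
) -> PpvCurve:
    """Precision among the top k, for k up to a fraction of the list.

    ppv(k) = |top-k ∩ positives| / k; the normalizer is the prevalence of
    positives over the whole ranked list (the expected precision of a
    random ordering at any depth). Callers exclude items without a score
    before ranking.
    """
    n = len(ranked)
    if n == 0:
        raise ValidationError("empty ranking")
    hits = np.fromiter((item in gold.positives for item in ranked), bool, n)
    p = int(hits.sum())
    if p == 0:
        raise ValidationError("no gold positive present in the ranked universe")
    prevalence = p / n
    kmax = max(1, math.floor(max_depth_fraction * n))
    ks = np.arange(1, kmax + 1)
    ppv = np.cumsum(hits)[:kmax] / ks
    return PpvCurve(
        ks=ks, ppv=ppv, normalized_ppv=ppv / prevalence, prevalence=prevalence
    )


def tp_rate_at_percentile(
    ranked: Sequence[Hashable], gold: GoldStandard, pct: float
) -> float:
    """Percentage of gold positives among the top n = pct% of the ranking.

    n = floor(pct/100 * N) with a minimum of 1.
    """
    if not (0 < pct <= 100):
        raise ValidationError("percentile must lie in (0, 100]")
    n_total = len(ranked)
    if n_total == 0:
        raise ValidationError("empty ranking")
    n = max(1, math.floor(pct / 100 * n_total))
    hits = sum(1 for item in ranked[:n] if item in gold.positives)
    return 100.0 * hits / n


@dataclass
class BootstrapSummary:
    """Replicate TP rates per percentile with means and percentile CIs."""

    percentiles: tuple[float, ...]
    replicates: dict[float, np.ndarray]
    mean: dict[float, float] = field(default_factory=dict)
    ci_low: dict[float, float] = field(default_factory=dict)
    ci_high: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        for pct, reps in self.replicates.items():
            self.mean[pct] = float(np.mean(reps))
            self.ci_low[pct] = float(np.quantile(reps, 0.025))
            self.ci_high[pct] = float(np.quantile(reps, 0.975))

    def to_dict(self) -> dict:
        return {
            str(pct): {
                "mean": self.mean[pct],
                "ci_low": self.ci_low[pct],
                "ci_high": self.ci_high[pct],
                "replicates": [float(v) for v in self.replicates[pct]],
            }
            for pct in self.percentiles
        }


def bootstrap_tp(
    ranked: Sequence[Hashable],
    gold: GoldStandard,
    reps: int = 100,
    frac: float = 0.8,
    pcts: Sequence[float] = (1.0, 5.0, 10.0),
    seed: int | np.random.Generator | None = None,
    replace: bool = False,
) -> BootstrapSummary:
    """TP rates under resampling of the gold standard.

    Each replicate keeps floor(frac * |gold|) positives — drawn without
    replacement by default (subsampling; ``replace=True`` gives a classical
    bootstrap) — and recomputes the TP rate at every percentile. The CI is
    the (0.025, 0.975) percentile interval of the replicate distribution.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not (0 < frac <= 1):
        raise ValidationError("frac must lie in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = sorted(gold.positives, key=repr)
    m = math.floor(frac * len(pool))
    if m < 2:
        raise ValidationError("gold standard smaller than 2 after sampling")
    replicates = {float(p): np.empty(reps) for p in pcts}
    for r in range(reps):
        idx = rng.choice(len(pool), size=m, replace=replace)
        sample = GoldStandard({pool[i] for i in idx}, label=gold.label)
        for p in pcts:
            replicates[float(p)][r] = tp_rate_at_percentile(ranked, sample, p)
    return BootstrapSummary(
        percentiles=tuple(float(p) for p in pcts), replicates=replicates
    )


def compare_methods(replicate_matrix: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA plus Tukey HSD over per-method replicate TP rates.

    Requires >=2 methods with equal replicate counts. Returns the F
    statistic and p-value, and per pair the mean difference, Tukey-adjusted
    p (studentized range) and Benjamini-Hochberg-adjusted p across pairs.
    With no variance anywhere and equal means, F is defined as 0 and p = 1.
    """
    methods = sorted(replicate_matrix)
    if len(methods) < 2:
        raise ValidationError("need at least two methods")
    groups = [np.asarray(replicate_matrix[m], dtype=float) for m in methods]
    n = len(groups[0])
    if any(len(g) != n for g in groups):
        raise ValidationError("replicate counts differ between methods")
    if n < 2:
        raise ValidationError("need at least two replicates per method")
    k = len(groups)
    total_n = k * n
    grand = float(np.mean(np.concatenate(groups)))
    means = [float(np.mean(g)) for g in groups]
    ss_between = n * sum((m - grand) ** 2 for m in means)
    ss_within = sum(float(np.sum((g - m) ** 2)) for g, m in zip(groups, means))
    df_between = k - 1
    df_within = total_n - k
    if ss_within == 0 and ss_between == 0:
        f_stat, p_value = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_value = math.inf, 0.0
    else:
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        f_stat = ms_between / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    ms_within = ss_within / df_within

    pairs = []
    raw_p = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(methods), 2):
        diff = means[ia] - means[ib]
        if ms_within == 0:
            p_tukey = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / math.sqrt(ms_within / n)
            p_tukey = float(stats.studentized_range.sf(q, k, df_within))
        pairs.append({"a": a, "b": b, "diff": diff, "p_tukey": p_tukey})
        raw_p.append(p_tukey)
    if pairs:
        _, p_bh, _, _ = multipletests(raw_p, method="fdr_bh")
        for pair, adj in zip(pairs, p_bh):
            pair["p_bh"] = float(adj)
    return {
        "anova": {
            "F": f_stat,
            "p": p_value,
            "df_between": df_between,
            "df_within": df_within,
        },
        "tukey": pairs,
    }


def benchmark_report(
    rankings: Mapping[str, Sequence[Hashable]],
    gold: GoldStandard,
    pcts: Sequence[float] = (1.0, 5.0, 10.0),
    reps: int = 100,
    frac: float = 0.8,
    seed: int | None = None,
    max_depth_fraction: float = 0.5,
) -> dict:
    """Full benchmark: curves, point TP rates, bootstrap and comparisons."""
    rng = np.random.default_rng(seed)
    report: dict = {"label": gold.label, "methods": {}, "seed": seed}
    replicate_matrix: dict[str, dict[float, np.ndarray]] = {}
    for name in sorted(rankings):
        ranked = list(rankings[name])
        curve = ppv_curve(ranked, gold, max_depth_fraction)
        boot = bootstrap_tp(ranked, gold, reps=reps, frac=frac, pcts=pcts, seed=rng)
        report["methods"][name] = {
            "n_ranked": len(ranked),
            "prevalence": curve.prevalence,
            "ppv_depths": [int(curve.ks[-1])],
            "normalized_ppv_at_max_depth": float(curve.normalized_ppv[-1]),
            "tp_rates": {
                str(p): tp_rate_at_percentile(ranked, gold, p) for p in pcts
            },
            "bootstrap": boot.to_dict(),
        }
        replicate_matrix[name] = boot.replicates
    if len(rankings) >= 2:
        report["comparison"] = {
            str(p): compare_methods(
                {m: replicate_matrix[m][float(p)] for m in replicate_matrix}
            )
            for p in pcts
        }
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a benchmark report to strict JSON (non-finite -> null)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
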