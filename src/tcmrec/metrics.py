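"""Ranking-evaluation suite: AUC, Hits@k, mean rank, MRR and unit hit rate.

Hits@k is per-sample label recall in the top k, averaged over samples.
Mean rank and MRR expand each multi-label sample into one evaluation unit
per true label by default (``unit="per_label"``); ``unit="best"`` scores
only the best-ranked true label per sample.  The unit hit rate is a
positional metric: at each rank position k, the fraction of samples whose
k-th ranked prediction is a true label; ``hits_avg`` averages positions
1-3.  AUC uses the Mann-Whitney convention with ties counted one half.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class RankedPrediction:
    """Per-sample ordered candidates (rank 1 first) with the true label set."""

    sample_id: str
    ranked_elements: list
    scores: list[float]
    label_set: set

    def __post_init__(self):
        if len(set(self.ranked_elements)) != len(self.ranked_elements):
            raise ValueError(f"{self.sample_id}: duplicate elements in ranking")


@dataclass
class ScoredSample:
    score: float
    is_positive: bool


@dataclass
class MetricReport:
    auc: float
    hits_at_10: float
    mean_rank: float
    mrr: float
    unit_hit_rate: list[float]
    hits_avg: float
    n_samples: int
    per_task: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def auc(samples: list[ScoredSample]) -> float:
    """Pairwise ranking AUC; ties between classes count one half."""
    pos = np.array([s.score for s in samples if s.is_positive], dtype=float)
    neg = np.array([s.score for s in samples if not s.is_positive], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ValueError("AUC: non-finite score")
    # rank-based Mann-Whitney; O((n+m) log(n+m))
    allsc = np.concatenate([pos, neg])
    order = np.argsort(allsc, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    sorted_sc = allsc[order]
    i = 0
    n = allsc.size
    while i < n:
        j = i
        while j + 1 < n and sorted_sc[j + 1] == sorted_sc[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[:pos.size].sum()
    return (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


def hits_at_k(pred: RankedPrediction, k: int) -> float:
    """|label_set ∩ top-k| / |label_set| for one sample."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not pred.label_set:
        raise ValueError(f"{pred.sample_id}: empty label set")
    top = set(pred.ranked_elements[:k])
    return len(pred.label_set & top) / len(pred.label_set)


def corpus_hits_at_k(preds: list[RankedPrediction], k: int) -> float:
    vals = []
    for p in preds:
        if not p.label_set:
            log.warning("hits@k: sample %s skipped (no labels)", p.sample_id)
            continue
        vals.append(hits_at_k(p, k))
    if not vals:
        raise ValueError("no evaluable samples")
    return float(np.mean(vals))


def _label_ranks(pred: RankedPrediction, vocab_size: int | None) -> list[int]:
    pos = {el: i + 1 for i, el in enumerate(pred.ranked_elements)}
    fallback = (vocab_size or len(pred.ranked_elements)) + 1
    ranks = []
    for label in sorted(pred.label_set, key=repr):
        r = pos.get(label)
        if r is None:
            log.warning("rank: label %r of %s absent from ranking; rank=%d",
                        label, pred.sample_id, fallback)
            r = fallback
        ranks.append(r)
    return ranks


def _evaluation_units(preds: list[RankedPrediction], unit: str,
                      vocab_size: int | None) -> list[int]:
    units: list[int] = []
    for p in preds:
        ranks = _label_ranks(p, vocab_size)
        if unit == "per_label":
            units.extend(ranks)
        elif unit == "best":
            units.append(min(ranks))
        else:
            raise ValueError(f"unknown unit {unit!r}")
    return units


def mean_rank(preds: list[RankedPrediction], unit: str = "per_label",
              vocab_size: int | None = None) -> float:
    units = _evaluation_units(preds, unit, vocab_size)
    return float(np.mean(units))


def mrr(preds: list[RankedPrediction], unit: str = "per_label",
        vocab_size: int | None = None) -> float:
    units = _evaluation_units(preds, unit, vocab_size)
    return float(np.mean([1.0 / r for r in units]))


def unit_hit_rate(preds: list[RankedPrediction], k_max: int = 10
                  ) -> tuple[np.ndarray, float]:
    """Positional hit rates for ranks 1..k_max and their 1-3 average.

    Position k's value is the fraction of samples whose k-th ranked
    prediction is one of that sample's true labels; rankings shorter than
    ``k_max`` count the missing positions as misses (flagged).
    """
    if not preds:
        raise ValueError("no samples")
    rates = np.zeros(k_max)
    for p in preds:
        if len(p.ranked_elements) < k_max:
            log.warning("unit_hit_rate: ranking of %s shorter than k_max=%d",
                        p.sample_id, k_max)
        for k in range(1, k_max + 1):
            if k <= len(p.ranked_elements) and p.ranked_elements[k - 1] in p.label_set:
                rates[k - 1] += 1
    rates /= len(preds)
    hits_avg = float(rates[:3].mean())
    return rates, hits_avg


def auc_from_predictions(preds: list[RankedPrediction]) -> float:
    """AUC over all (case, candidate) scores pooled across samples."""
    samples = [ScoredSample(score=s, is_positive=(el in p.label_set))
               for p in preds for el, s in zip(p.ranked_elements, p.scores)]
    return auc(samples)


def build_report(preds: list[RankedPrediction], vocab_size: int | None = None,
                 unit: str = "per_label", k_max: int = 10,
                 per_task: dict[str, dict] | None = None) -> MetricReport:
    rates, hits_avg = unit_hit_rate(preds, k_max=k_max)
    return MetricReport(
        auc=auc_from_predictions(preds),
        hits_at_10=corpus_hits_at_k(preds, 10),
        mean_rank=mean_rank(preds, unit=unit, vocab_size=vocab_size),
        mrr=mrr(preds, unit=unit, vocab_size=vocab_size),
        unit_hit_rate=[float(v) for v in rates],
        hits_avg=hits_avg,
        n_samples=len(preds),
        per_task=per_task or {},
    )


def paired_bootstrap(per_sample_a: list[float], per_sample_b: list[float],
                     n_boot: int = 2000, seed: int = 0) -> dict:
    """Generic paired bootstrap over per-sample metric values.

    Resamples cases with replacement and reports the mean difference
    (a - b), its 95% interval, and the fraction of resamples in which
    system a does not beat system b (a one-sided exceedance proportion,
    not a formal p-value).
    """
    a = np.asarray(per_sample_a, dtype=float)
    b = np.asarray(per_sample_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length nonempty per-sample vectors")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    diffs = (a[idx] - b[idx]).mean(axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"mean_diff": float(a.mean() - b.mean()),
            "ci_low": float(lo), "ci_high": float(hi),
            "p_not_better": float(np.mean(diffs <= 0.0)),
            "n_boot": n_boot}


def unit_hit_rate_table(preds: list[RankedPrediction], path: str | Path,
                        k_max: int = 10) -> None:
    """Write the per-position unit-hit-rate vector as a TSV table."""
    rates, hits_avg = unit_hit_rate(preds, k_max=k_max)
    lines = ["position\tunit_hit_rate"]
    lines += [f"{k + 1}\t{rates[k]:.6f}" for k in range(k_max)]
    lines.append(f"avg_1_3\t{hits_avg:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
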