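"""Symptom/element association statistics.

All counts are per-case presence counts (a token or token pair is counted
at most once per consultation); only term frequency uses raw within-case
multiplicity.  The five statistics:

* co-occurrence probability  P(b|a) = count(a,b) / count(a,B)
  where count(a,B) is the number of cases containing symptom ``a`` and at
  least one evidence element;
* confidence(A=>B) = count(A ∩ B) / count(A), item sets over cases;
* support(A=>B)    = count(A ∩ B) / count(T);
* TF(token, case)  = n_ij / Σ_k n_kj over the case's element list
  (configurable to symptom lists);
* IDF(token)       = ln(N / (n_i + 1))  — natural log; a token present in
  every case yields ln(N/(N+1)) < 0 and is kept as computed.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus import CaseRecord

log = logging.getLogger(__name__)


@dataclass
class AssociationStats:
    """Pairwise/marginal counts from a corpus scan, plus TF bookkeeping."""

    n_cases: int = 0
    pair_count: dict[tuple[str, str], int] = field(default_factory=dict)
    symptom_any_count: dict[str, int] = field(default_factory=dict)
    doc_freq: dict[str, int] = field(default_factory=dict)
    case_token_totals: dict[str, int] = field(default_factory=dict)
    case_term_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    case_item_sets: dict[str, frozenset] = field(default_factory=dict)
    doc_field: str = "elements"

    # -- queries ----------------------------------------------------------
    def itemset_count(self, items) -> int:
        """Number of cases whose symptom∪element token set contains ``items``."""
        items = frozenset(items)
        if not items:
            return self.n_cases
        return sum(1 for s in self.case_item_sets.values() if items <= s)

    # -- serialization (feature store) ------------------------------------
    def to_records(self) -> list[dict]:
        recs: list[dict] = [{"kind": "meta", "n_cases": self.n_cases,
                             "doc_field": self.doc_field}]
        recs += [{"kind": "pair", "a": a, "b": b, "n": n}
                 for (a, b), n in sorted(self.pair_count.items())]
        recs += [{"kind": "symptom_any", "a": a, "n": n}
                 for a, n in sorted(self.symptom_any_count.items())]
        recs += [{"kind": "doc_freq", "t": t, "n": n}
                 for t, n in sorted(self.doc_freq.items())]
        for cid in sorted(self.case_item_sets):
            recs.append({"kind": "case", "id": cid,
                         "total": self.case_token_totals.get(cid, 0),
                         "terms": dict(sorted(self.case_term_counts.get(cid, {}).items())),
                         "items": sorted(self.case_item_sets[cid])})
        return recs

    @classmethod
    def from_records(cls, records: list[dict]) -> "AssociationStats":
        out = cls()
        for rec in records:
            kind = rec["kind"]
            if kind == "meta":
                out.n_cases = rec["n_cases"]
                out.doc_field = rec.get("doc_field", "elements")
            elif kind == "pair":
                out.pair_count[(rec["a"], rec["b"])] = rec["n"]
            elif kind == "symptom_any":
                out.symptom_any_count[rec["a"]] = rec["n"]
            elif kind == "doc_freq":
                out.doc_freq[rec["t"]] = rec["n"]
            elif kind == "case":
                out.case_token_totals[rec["id"]] = rec["total"]
                out.case_term_counts[rec["id"]] = {k: int(v)
                                                   for k, v in rec["terms"].items()}
                out.case_item_sets[rec["id"]] = frozenset(rec["items"])
        return out


def build_association_stats(cases: list[CaseRecord],
                            doc_field: str = "elements") -> AssociationStats:
    """Single-pass presence counts over the corpus.

    ``doc_field`` chooses which token list forms the TF/IDF "document"
    (default: the case's evidence-element list).
    """
    if not cases:
        raise ValueError("no cases")
    if doc_field not in ("elements", "symptoms"):
        raise ValueError(f"doc_field must be 'elements' or 'symptoms', got {doc_field!r}")
    stats = AssociationStats(doc_field=doc_field)
    stats.n_cases = len(cases)
    for rec in cases:
        sym_set = set(rec.symptoms)
        elem_set = set(rec.elements)
        for t in sym_set | elem_set:
            stats.doc_freq[t] = stats.doc_freq.get(t, 0) + 1
        if elem_set:
            for a in sym_set:
                stats.symptom_any_count[a] = stats.symptom_any_count.get(a, 0) + 1
                for b in elem_set:
                    key = (a, b)
                    stats.pair_count[key] = stats.pair_count.get(key, 0) + 1
        doc = rec.elements if doc_field == "elements" else rec.symptoms
        counts = Counter(doc)
        stats.case_term_counts[rec.case_id] = dict(counts)
        stats.case_token_totals[rec.case_id] = sum(counts.values())
        stats.case_item_sets[rec.case_id] = frozenset(sym_set | elem_set)
    return stats


def cooccurrence_probability(stats: AssociationStats, a: str, b: str) -> float:
    """P(element b | symptom a), over cases where ``a`` meets any element."""
    denom = stats.symptom_any_count.get(a, 0)
    if denom == 0:
        log.warning("co-occurrence: symptom %r never co-occurs with elements", a)
        return 0.0
    return stats.pair_count.get((a, b), 0) / denom


def confidence(stats: AssociationStats, A, B) -> float:
    """confidence(A=>B) = count(A∩B)/count(A); 0 with a warning if count(A)=0."""
    A, B = frozenset(A), frozenset(B)
    denom = stats.itemset_count(A)
    if denom == 0:
        log.warning("confidence: antecedent %s occurs in no case", sorted(A))
        return 0.0
    return stats.itemset_count(A | B) / denom


def support(stats: AssociationStats, A, B) -> float:
    """support(A=>B) = count(A∩B)/count(T)."""
    return stats.itemset_count(frozenset(A) | frozenset(B)) / stats.n_cases


def tf(stats: AssociationStats, token: str, case_id: str) -> float:
    """Term frequency of ``token`` within one case's document."""
    if case_id not in stats.case_token_totals:
        raise KeyError(f"unknown case_id {case_id!r}")
    total = stats.case_token_totals[case_id]
    if total == 0:
        log.warning("tf: case %r has an empty document", case_id)
        return 0.0
    return stats.case_term_counts[case_id].get(token, 0) / total


def idf(stats: AssociationStats, token: str) -> float:
    """Inverse document frequency ln(N / (n_i + 1))."""
    n_i = stats.doc_freq.get(token, 0)
    return math.log(stats.n_cases / (n_i + 1))


def tfidf(stats: AssociationStats, token: str, case_id: str) -> float:
    return tf(stats, token, case_id) * idf(stats, token)


def export_table(stats: AssociationStats, path: str | Path | None = None) -> pd.DataFrame:
    """Flat (symptom, element) table of all pairwise statistics, for inspection."""
    rows = []
    for (a, b), n in sorted(stats.pair_count.items()):
        rows.append({
            "symptom": a,
            "element": b,
            "pair_count": n,
            "cooccurrence": cooccurrence_probability(stats, a, b),
            "confidence": confidence(stats, {a}, {b}),
            "support": support(stats, {a}, {b}),
            "idf_element": idf(stats, b),
        })
    frame = pd.DataFrame(rows, columns=["symptom", "element", "pair_count",
                                        "cooccurrence", "confidence", "support",
                                        "idf_element"])
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
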