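"""Precision / recall / F1 accounting for token labels, entity spans, and the
document-level inhibitor protocol.

Conventions:

* precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean; any metric
  with a zero denominator is defined as 0.
* Token-label metrics are one-vs-rest per label, and the macro row is the
  unweighted mean over all labels **including O** — this matches how the
  per-label tables of SOBIE taggers are conventionally averaged.
* Entity-level metrics require exact (doc, section, start, end) agreement; a
  prediction off by one character counts as both a false positive and a false
  negative.
* The inhibitor protocol counts unique normalized names per document: a
  recognized name absent from the gold list is one FP, a gold name never
  recognized in its document is one FN.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import Document
from .textprep import LabeledSequence

__all__ = [
    "EvalCounts",
    "MetricsReport",
    "prf",
    "f1_score",
    "macro_average",
    "token_label_metrics",
    "entity_metrics",
    "inhibitor_eval",
    "normalize_name",
]

_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")


def normalize_name(name: str) -> str:
    """Case-fold and strip flanking punctuation/whitespace from a mention."""
    s = name.casefold().strip()
    start, end = 0, len(s)
    while start < end and s[start] in _PUNCT:
        start += 1
    while end > start and s[end - 1] in _PUNCT:
        end -= 1
    return " ".join(s[start:end].split())


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be >= 0")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) with the zero-denominator-is-zero convention."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    return p, r, f1_score(p, r)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average(per_label: dict[str, tuple[float, float, float]]) -> tuple[float, float, float]:
    """Unweighted mean of per-label (P, R, F1) triples."""
    n = len(per_label)
    if n == 0:
        return 0.0, 0.0, 0.0
    sp = sum(v[0] for v in per_label.values())
    sr = sum(v[1] for v in per_label.values())
    sf = sum(v[2] for v in per_label.values())
    return sp / n, sr / n, sf / n


@dataclass
class MetricsReport:
    """Per-label and macro-averaged (P, R, F1) plus the underlying counts."""

    per_label: dict[str, tuple[float, float, float]]
    macro: tuple[float, float, float]
    counts: dict[str, EvalCounts]

    def rounded(self, decimals: int = 4) -> dict:
        """Display form: tables are conventionally printed at 4 decimals
        (per-label SOBIE/type tables) or 2 (document-level tables)."""
        return {
            "per_label": {
                k: tuple(round(x, decimals) for x in v) for k, v in self.per_label.items()
            },
            "macro": tuple(round(x, decimals) for x in self.macro),
        }


def token_label_metrics(
    gold: list[LabeledSequence], pred: list[LabeledSequence]
) -> MetricsReport:
    """One-vs-rest token metrics over aligned gold/predicted sequences."""
    if len(gold) != len(pred):
        raise ValueError("gold/pred sequence count mismatch")
    labels: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for g, p in zip(gold, pred):
        if len(g.labels) != len(p.labels):
            raise ValueError(f"{g.doc_id}/{g.section}: token alignment mismatch")
        for gl, pl in zip(g.labels, p.labels):
            pairs.append((gl, pl))
            labels.add(gl)
            labels.add(pl)
    counts = {lab: EvalCounts() for lab in sorted(labels)}
    for gl, pl in pairs:
        if gl == pl:
            counts[gl].TP += 1
        else:
            counts[pl].FP += 1
            counts[gl].FN += 1
    per_label = {lab: prf(c) for lab, c in counts.items()}
    return MetricsReport(per_label, macro_average(per_label), counts)


def _span_keys(docs: list[Document], layer: str, entity_class: str | None):
    keys = set()
    for doc in docs:
        spans = doc.entities if layer == "gold" else doc.predicted
        for s in spans:
            if entity_class is None or s.entity_class == entity_class:
                keys.add((doc.doc_id, s.section, s.start, s.end))
    return keys


def entity_metrics(
    gold_spans, pred_spans
) -> tuple[EvalCounts, tuple[float, float, float]]:
    """Exact-span matching.

    Inputs are iterables of hashable span identities — use
    ``(doc_id, section, start, end)`` tuples, or pass Documents through
    :func:`entity_metrics_for_docs`.
    """
    gold = set(gold_spans)
    pred = set(pred_spans)
    counts = EvalCounts(TP=len(gold & pred), FP=len(pred - gold), FN=len(gold - pred))
    return counts, prf(counts)


def entity_metrics_for_docs(
    docs: list[Document], entity_class: str | None = None
) -> tuple[EvalCounts, tuple[float, float, float]]:
    """Exact-span metrics of each document's predicted layer against its gold layer."""
    return entity_metrics(
        _span_keys(docs, "gold", entity_class), _span_keys(docs, "pred", entity_class)
    )


def inhibitor_eval(
    candidates: dict[str, set[str]], gold: dict[str, set[str]]
) -> tuple[EvalCounts, tuple[float, float, float]]:
    """Document-level name evaluation.

    ``candidates`` maps doc_id to the set of recognized (normalized) chemical
    names; ``gold`` maps doc_id to the true inhibitor names, normalized
    identically.  Per document: each recognized name not in gold adds one FP,
    each gold name not recognized adds one FN, each recognized gold name one TP.
    """
    total = EvalCounts()
    for doc_id in sorted(set(candidates) | set(gold)):
        cand = candidates.get(doc_id, set())
        true = gold.get(doc_id, set())
        total = total + EvalCounts(
            TP=len(cand & true), FP=len(cand - true), FN=len(true - cand)
        )
    return total, prf(total)
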