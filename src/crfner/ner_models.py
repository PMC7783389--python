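"""The four taggers and the cross-validation harness.

Model (i) tags chemical mentions with SOBIE labels; model (ii) does the same
for gene/protein mentions; model (iii) labels tokens inside chemical mentions
with the mention's surface class (the seven chemical types) and O elsewhere;
model (iv) is the sequential composition applied to fresh documents: decode
chemical spans, assign each a type by majority vote of the type model over its
tokens, then decode gene spans independently.  A token may end up in both a
chemical and a gene span; both layers are kept.

Sequences are built per document section (title and abstract separately), so
feature context windows never cross a section boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from . import crf_core
from .corpus_io import ABSTRACT, TITLE, CHEMICAL_TYPES, Document
from .crf_core import CRFConfig, CRFModel
from .evaluation import EvalCounts, MetricsReport, token_label_metrics
from .features import Lexicon, default_lexicons, rule_pos_tag, sequence_features
from .textprep import SOBIE_LABELS, LabeledSequence, sobie_decode, sobie_encode, tokenize

__all__ = [
    "CVConfig",
    "CVResult",
    "TaggerBundle",
    "doc_sequences",
    "train_span_model",
    "train_type_model",
    "apply_combined",
    "cross_validate",
]


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation settings; the split unit is the document."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def doc_sequences(doc: Document) -> list[tuple[str, str, list]]:
    """(section, text, tokens) for each non-empty section of a document."""
    out = []
    for section, text in ((TITLE, doc.title), (ABSTRACT, doc.abstract)):
        tokens = tokenize(text)
        if tokens:
            out.append((section, text, tokens))
    return out


def _span_training_data(
    corpus: list[Document],
    entity_class: str,
    lexicons: list[Lexicon],
    pos_provider,
) -> tuple[list, list[LabeledSequence]]:
    data = []
    gold_seqs = []
    for doc in corpus:
        for section, _text, tokens in doc_sequences(doc):
            spans = [
                e for e in doc.entities if e.section == section and e.entity_class == entity_class
            ]
            labels = sobie_encode(tokens, spans)
            feats = sequence_features(tokens, pos_provider, lexicons)
            data.append((feats, labels))
            gold_seqs.append(LabeledSequence(doc.doc_id, section, tokens, labels))
    return data, gold_seqs


def train_span_model(
    corpus: list[Document],
    entity_class: str,
    config: CRFConfig | None = None,
    lexicons: list[Lexicon] | None = None,
    pos_provider=rule_pos_tag,
) -> CRFModel:
    """Fit a SOBIE tagger for one entity class (model i or ii)."""
    if entity_class not in ("CHEMICAL", "GENE"):
        raise ValueError(f"bad entity_class {entity_class!r}")
    if not any(e.entity_class == entity_class for d in corpus for e in d.entities):
        raise ValueError(f"corpus has no {entity_class} annotations")
    lexicons = lexicons if lexicons is not None else default_lexicons()
    data, _ = _span_training_data(corpus, entity_class, lexicons, pos_provider)
    return crf_core.fit(data, config, alphabet=tuple(sorted(SOBIE_LABELS)))


def _type_labels(tokens: list, doc: Document, section: str) -> list[str]:
    labels = ["O"] * len(tokens)
    for span in doc.entities:
        if span.section != section or span.entity_class != "CHEMICAL":
            continue
        if span.entity_type not in CHEMICAL_TYPES:
            continue
        for i, t in enumerate(tokens):
            if t.start < span.end and t.end > span.start:
                labels[i] = span.entity_type
    return labels


def train_type_model(
    corpus: list[Document],
    config: CRFConfig | None = None,
    lexicons: list[Lexicon] | None = None,
    pos_provider=rule_pos_tag,
) -> CRFModel:
    """Fit the chemical-type tagger (model iii): token label = the enclosing
    chemical mention's type, O outside mentions."""
    if not any(
        e.entity_class == "CHEMICAL" and e.entity_type in CHEMICAL_TYPES
        for d in corpus
        for e in d.entities
    ):
        raise ValueError("corpus has no typed chemical annotations")
    lexicons = lexicons if lexicons is not None else default_lexicons()
    data = []
    for doc in corpus:
        for section, _text, tokens in doc_sequences(doc):
            feats = sequence_features(tokens, pos_provider, lexicons)
            data.append((feats, _type_labels(tokens, doc, section)))
    return crf_core.fit(data, config)


def _majority_type(span_token_idx: list[int], type_labels: list[str]) -> str:
    votes = [type_labels[i] for i in span_token_idx if type_labels[i] != "O"]
    if not votes:
        return "UNSPECIFIED"
    tally: dict[str, int] = {}
    for v in votes:
        tally[v] = tally.get(v, 0) + 1
    best = max(tally.values())
    tied = {t for t, n in tally.items() if n == best}
    for v in votes:  # earliest vote among the tied types
        if v in tied:
            return v
    return "UNSPECIFIED"  # unreachable


@dataclass
class TaggerBundle:
    """Models (i)-(iii) plus the lexicons and POS provider they were trained
    with; together they realize the combined tagger (iv)."""

    chem_model: CRFModel
    gene_model: CRFModel
    type_model: CRFModel
    lexicons: list[Lexicon] = field(default_factory=default_lexicons)
    pos_provider_id: str = "rule"
    version: str = "1"

    def pos_provider(self):
        if self.pos_provider_id != "rule":
            raise ValueError(f"unknown POS provider {self.pos_provider_id!r}")
        return rule_pos_tag

    def lexicon_hashes(self) -> list[str]:
        return [_lexicon_hash(lex) for lex in self.lexicons]

    def save(self, path) -> None:
        payload = {
            "version": self.version,
            "pos_provider_id": self.pos_provider_id,
            "lexicon_hashes": self.lexicon_hashes(),
            "lexicons": [
                {"tag": lex.tag, "entries": sorted(lex.entries)} for lex in self.lexicons
            ],
            "chem_model": _model_to_dict(self.chem_model),
            "gene_model": _model_to_dict(self.gene_model),
            "type_model": _model_to_dict(self.type_model),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path, lexicons: list[Lexicon] | None = None) -> "TaggerBundle":
        """Load a saved bundle.  If ``lexicons`` is given, their hashes must
        match the ones stored at save time: weights are meaningless if the
        feature atoms change under them."""
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        stored = [
            Lexicon(frozenset(d["entries"]), d["tag"]) for d in payload["lexicons"]
        ]
        if lexicons is not None:
            if [_lexicon_hash(l) for l in lexicons] != payload["lexicon_hashes"]:
                raise ValueError("lexicon hash mismatch: refusing to load bundle")
            stored = lexicons
        return cls(
            chem_model=_model_from_dict(payload["chem_model"]),
            gene_model=_model_from_dict(payload["gene_model"]),
            type_model=_model_from_dict(payload["type_model"]),
            lexicons=stored,
            pos_provider_id=payload["pos_provider_id"],
            version=payload["version"],
        )


def _lexicon_hash(lex: Lexicon) -> str:
    h = hashlib.sha256()
    h.update(lex.tag.encode())
    for term in sorted(lex.entries):
        h.update(b"\0" + term.encode())
    return h.hexdigest()


def _model_to_dict(model: CRFModel) -> dict:
    return {
        "label_alphabet": list(model.label_alphabet),
        "feature_index": model.feature_index,
        "state_weights": model.state_weights.tolist(),
        "transition_weights": model.transition_weights.tolist(),
        "config": {
            "c1": model.config.c1,
            "c2": model.config.c2,
            "max_iterations": model.config.max_iterations,
            "tolerance": model.config.tolerance,
            "seed": model.config.seed,
        },
        "converged": model.converged,
    }


def _model_from_dict(d: dict) -> CRFModel:
    return CRFModel(
        label_alphabet=tuple(d["label_alphabet"]),
        feature_index=d["feature_index"],
        state_weights=np.array(d["state_weights"], dtype=np.float64).reshape(
            len(d["feature_index"]), len(d["label_alphabet"])
        ),
        transition_weights=np.array(d["transition_weights"], dtype=np.float64),
        config=CRFConfig(**d["config"]),
        converged=d["converged"],
    )


def apply_combined(bundle: TaggerBundle, doc: Document) -> Document:
    """Run the combined tagger (iv) on one document.

    Returns a copy carrying predicted entities; the input is never mutated.
    Chemical spans are decoded from the chemical SOBIE model and typed by
    token-majority vote of the type model (tie -> the earliest vote; no vote
    -> UNSPECIFIED); gene spans are decoded independently from the gene model.
    """
    out = doc.copy()
    out.predicted = []
    pos_provider = bundle.pos_provider()
    for section, text, tokens in doc_sequences(doc):
        feats = sequence_features(tokens, pos_provider, bundle.lexicons)
        chem_labels = crf_core.viterbi_decode(bundle.chem_model, feats)
        type_labels = crf_core.viterbi_decode(bundle.type_model, feats)
        gene_labels = crf_core.viterbi_decode(bundle.gene_model, feats)
        for span in sobie_decode(text, tokens, chem_labels, section, "CHEMICAL"):
            idx = [
                i for i, t in enumerate(tokens) if t.start < span.end and t.end > span.start
            ]
            etype = _majority_type(idx, type_labels)
            out.predicted.append(
                span.__class__(
                    section=span.section,
                    start=span.start,
                    end=span.end,
                    text=span.text,
                    entity_class="CHEMICAL",
                    entity_type=etype,
                )
            )
        out.predicted.extend(sobie_decode(text, tokens, gene_labels, section, "GENE"))
    return out


@dataclass
class CVResult:
    """Per-fold metric reports and their unweighted mean."""

    folds: list[MetricsReport]
    mean: MetricsReport


def cross_validate(
    corpus: list[Document],
    entity_class: str,
    config: CRFConfig | None = None,
    cv: CVConfig | None = None,
    lexicons: list[Lexicon] | None = None,
    pos_provider=rule_pos_tag,
) -> CVResult:
    """Document-level k-fold cross-validation of a SOBIE span model.

    Folds partition the documents (sizes differ by at most one); each fold is
    held out once, the model is trained on the rest, and token-label metrics
    are computed on the held-out documents.  Fold assignment is a
    deterministic function of the seed.
    """
    cv = cv or CVConfig()
    if len(corpus) < cv.k:
        raise ValueError(f"{len(corpus)} documents < {cv.k} folds")
    lexicons = lexicons if lexicons is not None else default_lexicons()
    splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(corpus):
        train_docs = [corpus[i] for i in train_idx]
        test_docs = [corpus[i] for i in test_idx]
        model = train_span_model(train_docs, entity_class, config, lexicons, pos_provider)
        gold_seqs: list[LabeledSequence] = []
        pred_seqs: list[LabeledSequence] = []
        for doc in test_docs:
            for section, _text, tokens in doc_sequences(doc):
                spans = [
                    e
                    for e in doc.entities
                    if e.section == section and e.entity_class == entity_class
                ]
                gold_seqs.append(
                    LabeledSequence(doc.doc_id, section, tokens, sobie_encode(tokens, spans))
                )
                feats = sequence_features(tokens, pos_provider, lexicons)
                pred_seqs.append(
                    LabeledSequence(
                        doc.doc_id, section, tokens, crf_core.viterbi_decode(model, feats)
                    )
                )
        fold_reports.append(token_label_metrics(gold_seqs, pred_seqs))
    return CVResult(fold_reports, _mean_report(fold_reports))


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    labels = sorted({lab for r in reports for lab in r.per_label})
    per_label = {}
    counts = {}
    for lab in labels:
        triples = [r.per_label[lab] for r in reports if lab in r.per_label]
        per_label[lab] = tuple(float(np.mean([t[i] for t in triples])) for i in range(3))
        summed = EvalCounts()
        for r in reports:
            if lab in r.counts:
                summed = summed + r.counts[lab]
        counts[lab] = summed
    macro = tuple(
        float(np.mean([r.macro[i] for r in reports])) for i in range(3)
    )
    return MetricsReport(per_label, macro, counts)
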