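"""Offset-preserving tokenization and SOBIE span <-> label conversion.

Tokenization follows the word/punctuation rule: a token is a maximal run of
word characters (alphanumerics + underscore) or a maximal run of non-word,
non-space characters, so "sphingosine-1-phosphate" splits into five tokens.
Inter-token gaps are whitespace only, which makes the tokenizer lossless.

SOBIE is the five-label span encoding (Single, Out, Begin, Inside, End,
equivalent to BIOES): a one-token entity is S; a two-token entity is B,E; a
longer one B,I,...,E; everything else O.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus_io import EntitySpan

__all__ = [
    "SOBIE_LABELS",
    "Token",
    "LabeledSequence",
    "tokenize",
    "sobie_encode",
    "sobie_decode",
]

logger = logging.getLogger(__name__)

#: SOBIE label alphabet for span models.
SOBIE_LABELS = ("S", "O", "B", "I", "E")

_WORDPUNCT = re.compile(r"\w+|[^\w\s]+", re.UNICODE)


@dataclass(frozen=True)
class Token:
    """A token with its half-open code-point offsets into the source text."""

    text: str
    start: int
    end: int


@dataclass
class LabeledSequence:
    """Tokens of one document section plus one label per token."""

    doc_id: str
    section: str
    tokens: list[Token]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{self.doc_id}/{self.section}: {len(self.tokens)} tokens "
                f"vs {len(self.labels)} labels"
            )


def tokenize(text: str) -> list[Token]:
    """Split text into word/punctuation tokens with source offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _WORDPUNCT.finditer(text)]


def _covered_token_range(tokens: list[Token], span: EntitySpan) -> tuple[int, int]:
    """Indices [first, last] of tokens overlapping the span, or raise."""
    idx = [i for i, t in enumerate(tokens) if t.start < span.end and t.end > span.start]
    if not idx:
        raise ValueError(f"span {span.text!r} [{span.start}:{span.end}] covers no token")
    first, last = idx[0], idx[-1]
    if tokens[first].start != span.start or tokens[last].end != span.end:
        # Partial-token overlap: include the whole token, keep labels total.
        logger.warning(
            "span %r [%d:%d] not token-aligned; snapping to token boundaries [%d:%d]",
            span.text,
            span.start,
            span.end,
            tokens[first].start,
            tokens[last].end,
        )
    return first, last


def sobie_encode(tokens: list[Token], spans: list[EntitySpan]) -> list[str]:
    """Turn character-offset spans into per-token SOBIE labels.

    Spans must be non-overlapping; a span starting or ending inside a token is
    snapped outward to whole tokens (with a logged warning).
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping spans: {a.text!r} and {b.text!r}")
    labels = ["O"] * len(tokens)
    for span in ordered:
        first, last = _covered_token_range(tokens, span)
        if any(labels[i] != "O" for i in range(first, last + 1)):
            raise ValueError(f"span {span.text!r} overlaps an already-labeled token")
        if first == last:
            labels[first] = "S"
        else:
            labels[first] = "B"
            labels[last] = "E"
            for i in range(first + 1, last):
                labels[i] = "I"
    return labels


def sobie_decode(
    text: str,
    tokens: list[Token],
    labels: list[str],
    section: str,
    entity_class: str = "CHEMICAL",
    entity_type: str = "UNSPECIFIED",
) -> list[EntitySpan]:
    """Turn per-token SOBIE labels back into entity spans.

    On well-formed sequences this inverts :func:`sobie_encode` exactly.
    Ill-formed output (possible from an imperfect tagger) is repaired
    leniently and deterministically:

    * ``I`` or ``E`` with no open ``B`` opens an entity;
    * ``B`` followed by O/S/B closes as a single-token entity;
    * an entity still open at the end of the sequence is closed there.

    The mention text is the source slice from the first to the last token of
    the entity, so interior punctuation and spacing are preserved.
    """
    if len(tokens) != len(labels):
        raise ValueError(f"{len(tokens)} tokens vs {len(labels)} labels")
    spans: list[tuple[int, int]] = []  # (first_token, last_token) inclusive
    open_start: int | None = None
    for i, lab in enumerate(labels):
        if lab not in ("S", "O", "B", "I", "E"):
            raise ValueError(f"unknown SOBIE label {lab!r}")
        if lab == "O":
            if open_start is not None:
                spans.append((open_start, i - 1))
                open_start = None
        elif lab == "S":
            if open_start is not None:
                spans.append((open_start, i - 1))
                open_start = None
            spans.append((i, i))
        elif lab == "B":
            if open_start is not None:
                spans.append((open_start, i - 1))
            open_start = i
        elif lab == "I":
            if open_start is None:
                open_start = i  # lenient: stray I opens an entity
        else:  # E
            if open_start is None:
                spans.append((i, i))  # lenient: stray E is a one-token entity
            else:
                spans.append((open_start, i))
                open_start = None
    if open_start is not None:
        spans.append((open_start, len(labels) - 1))
    out = []
    for first, last in spans:
        start, end = tokens[first].start, tokens[last].end
        out.append(
            EntitySpan(
                section=section,
                start=start,
                end=end,
                text=text[start:end],
                entity_class=entity_class,
                entity_type=entity_type,
            )
        )
    return out
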