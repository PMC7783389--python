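"""Reading and writing abstract corpora with character-offset standoff annotations.

Two tab-separated dialects are supported, modelled on the public chemical /
gene-protein NER corpora:

* ``chemdner`` — abstracts file ``doc_id<TAB>title<TAB>abstract``; annotations
  file ``doc_id<TAB>{T|A}<TAB>start<TAB>end<TAB>text<TAB>type`` with offsets
  counted per section.
* ``chemprot`` — abstracts file identical; entity file
  ``doc_id<TAB>T<n><TAB>type<TAB>start<TAB>end<TAB>text`` with offsets counted
  against the concatenation ``title + TAB + abstract``.

Offsets are 0-based, half-open, and count Unicode code points.  Every span is
validated against its section text on read; corpora violating slice-equals-text
are rejected, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CHEMICAL_TYPES",
    "GENE_TYPES",
    "TITLE",
    "ABSTRACT",
    "EntitySpan",
    "Document",
    "CorpusError",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "read_corpus_files",
    "write_corpus",
    "merge_corpora",
]

TITLE = "TITLE"
ABSTRACT = "ABSTRACT"

#: The seven surface-form classes of chemical mentions.
CHEMICAL_TYPES = frozenset(
    {"ABBREVIATION", "FAMILY", "FORMULA", "IDENTIFIER", "MULTIPLE", "SYSTEMATIC", "TRIVIAL"}
)
#: Gene/protein mention types: normalizable (Y) or not (N).
GENE_TYPES = frozenset({"GENE-Y", "GENE-N"})

_SECTIONS = (TITLE, ABSTRACT)


class CorpusError(ValueError):
    """Base class for corpus I/O failures."""


class CorpusParseError(CorpusError):
    """A line did not match the dialect grammar."""


class CorpusValidationError(CorpusError):
    """An annotation violated a structural invariant (offsets, types, ids)."""


@dataclass(frozen=True)
class EntitySpan:
    """A standoff entity annotation addressing one section of a document.

    ``start``/``end`` are 0-based half-open code-point offsets into the section
    text; ``text`` must equal that slice.  ``entity_class`` is CHEMICAL or GENE;
    ``entity_type`` is one of the seven chemical types, GENE-Y/GENE-N, or
    UNSPECIFIED (used for predictions, where the fine type may be unknown).
    """

    section: str
    start: int
    end: int
    text: str
    entity_class: str
    entity_type: str = "UNSPECIFIED"

    def __post_init__(self) -> None:
        if self.section not in _SECTIONS:
            raise CorpusValidationError(f"bad section {self.section!r}")
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(
                f"bad offsets [{self.start}, {self.end}) for span {self.text!r}"
            )
        if self.entity_class not in ("CHEMICAL", "GENE"):
            raise CorpusValidationError(f"bad entity_class {self.entity_class!r}")
        if self.entity_type != "UNSPECIFIED":
            if self.entity_class == "CHEMICAL" and self.entity_type not in CHEMICAL_TYPES:
                raise CorpusValidationError(
                    f"type {self.entity_type!r} invalid for CHEMICAL span {self.text!r}"
                )
            if self.entity_class == "GENE" and self.entity_type not in GENE_TYPES:
                raise CorpusValidationError(
                    f"type {self.entity_type!r} invalid for GENE span {self.text!r}"
                )

    def validate_against(self, section_text: str) -> None:
        """Check slice-equals-text against the section this span addresses."""
        piece = section_text[self.start : self.end]
        if piece != self.text:
            raise CorpusValidationError(
                f"span {self.text!r} at {self.section}[{self.start}:{self.end}] "
                f"addresses {piece!r}"
            )


@dataclass
class Document:
    """One abstract: id, title, abstract text, gold and predicted entity layers."""

    doc_id: str
    title: str
    abstract: str
    entities: list[EntitySpan] = field(default_factory=list)
    predicted: list[EntitySpan] = field(default_factory=list)

    def section_text(self, section: str) -> str:
        if section == TITLE:
            return self.title
        if section == ABSTRACT:
            return self.abstract
        raise CorpusValidationError(f"bad section {section!r}")

    def validate(self) -> None:
        if not self.doc_id:
            raise CorpusValidationError("empty doc_id")
        for span in self.entities:
            span.validate_against(self.section_text(span.section))

    def copy(self) -> "Document":
        return Document(
            self.doc_id, self.title, self.abstract, list(self.entities), list(self.predicted)
        )


def _class_for_type(entity_type: str) -> str:
    if entity_type in CHEMICAL_TYPES or entity_type in ("CHEMICAL", "UNSPECIFIED"):
        return "CHEMICAL"
    if entity_type in GENE_TYPES:
        return "GENE"
    raise CorpusParseError(f"unknown entity type {entity_type!r}")


def _parse_abstracts(lines: list[str]) -> dict[str, Document]:
    docs: dict[str, Document] = {}
    for i, line in enumerate(lines, start=1):
        if line == "":
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusParseError(
                f"abstracts line {i}: expected 3 tab-separated fields, got {len(parts)}"
            )
        doc_id, title, abstract = parts
        if not doc_id:
            raise CorpusParseError(f"abstracts line {i}: empty doc_id")
        if doc_id in docs:
            raise CorpusValidationError(f"abstracts line {i}: duplicate doc_id {doc_id!r}")
        docs[doc_id] = Document(doc_id, title, abstract)
    return docs


def _resolve_chemprot_offsets(doc: Document, start: int, end: int):
    """Map a title<TAB>abstract concatenation offset pair to (section, start, end)."""
    tlen = len(doc.title)
    if end <= tlen:
        return TITLE, start, end
    if start >= tlen + 1:
        return ABSTRACT, start - tlen - 1, end - tlen - 1
    raise CorpusValidationError(
        f"doc {doc.doc_id}: span [{start}, {end}) crosses the title/abstract boundary"
    )


def read_corpus(abstracts_lines: list[str], annotation_lines: list[str], dialect: str) -> list[Document]:
    """Parse in-memory lines of the two files into validated Documents.

    One Document per abstracts line, in file order; each annotation is attached
    to its document and checked against the section text.
    """
    if dialect not in ("chemdner", "chemprot"):
        raise ValueError(f"unknown dialect {dialect!r}")
    docs = _parse_abstracts(abstracts_lines)
    for i, line in enumerate(annotation_lines, start=1):
        if line == "":
            continue
        parts = line.split("\t")
        if dialect == "chemdner":
            if len(parts) != 6:
                raise CorpusParseError(
                    f"annotations line {i}: expected 6 fields, got {len(parts)}"
                )
            doc_id, sec_code, s_start, s_end, text, etype = parts
            if sec_code not in ("T", "A"):
                raise CorpusParseError(f"annotations line {i}: bad section code {sec_code!r}")
            section = TITLE if sec_code == "T" else ABSTRACT
        else:
            if len(parts) != 6:
                raise CorpusParseError(
                    f"entities line {i}: expected 6 fields, got {len(parts)}"
                )
            doc_id, _tid, etype, s_start, s_end, text = parts
            section = None  # resolved from offsets below
        if doc_id not in docs:
            raise CorpusValidationError(
                f"annotations line {i}: unknown doc_id {doc_id!r}"
            )
        try:
            start, end = int(s_start), int(s_end)
        except ValueError as exc:
            raise CorpusParseError(f"annotations line {i}: non-integer offsets") from exc
        doc = docs[doc_id]
        if dialect == "chemprot":
            section, start, end = _resolve_chemprot_offsets(doc, start, end)
        span = EntitySpan(
            section=section,
            start=start,
            end=end,
            text=text,
            entity_class=_class_for_type(etype),
            entity_type=etype if etype != "CHEMICAL" else "UNSPECIFIED",
        )
        span.validate_against(doc.section_text(section))
        doc.entities.append(span)
    out = list(docs.values())
    for doc in out:
        doc.validate()
    return out


def read_corpus_files(abstracts_path, annotations_path, dialect: str) -> list[Document]:
    """File-path front end of :func:`read_corpus` (UTF-8, LF line endings)."""
    with open(abstracts_path, encoding="utf-8") as fh:
        abstracts = fh.read().split("\n")
    with open(annotations_path, encoding="utf-8") as fh:
        annotations = fh.read().split("\n")
    return read_corpus(abstracts, annotations, dialect)


def _check_serializable(value: str, what: str) -> str:
    if "\t" in value or "\n" in value:
        raise CorpusValidationError(f"{what} contains a delimiter character: {value!r}")
    return value


def write_corpus(docs: list[Document], dialect: str) -> tuple[str, str]:
    """Serialize documents (gold layer) into (abstracts text, annotations text).

    ``read_corpus(write_corpus(docs))`` reproduces the documents field for
    field.  To keep that identity in the chemprot dialect, the writer emits the
    specific chemical type when one is known (a dialect extension; plain
    CHEMICAL is written for UNSPECIFIED chemicals).
    """
    if dialect not in ("chemdner", "chemprot"):
        raise ValueError(f"unknown dialect {dialect!r}")
    abs_lines: list[str] = []
    ann_lines: list[str] = []
    for doc in docs:
        doc.validate()
        _check_serializable(doc.doc_id, f"doc_id of {doc.doc_id!r}")
        _check_serializable(doc.title, f"title of {doc.doc_id}")
        _check_serializable(doc.abstract, f"abstract of {doc.doc_id}")
        abs_lines.append(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}")
        for k, span in enumerate(doc.entities, start=1):
            _check_serializable(span.text, f"span text in {doc.doc_id}")
            if span.entity_class == "GENE" and span.entity_type == "UNSPECIFIED":
                raise CorpusValidationError(
                    f"doc {doc.doc_id}: GENE span {span.text!r} without GENE-Y/GENE-N "
                    "type cannot be serialized losslessly"
                )
            if dialect == "chemdner":
                sec = "T" if span.section == TITLE else "A"
                ann_lines.append(
                    f"{doc.doc_id}\t{sec}\t{span.start}\t{span.end}\t{span.text}\t"
                    f"{span.entity_type if span.entity_type != 'UNSPECIFIED' else 'CHEMICAL'}"
                )
            else:
                offset = 0 if span.section == TITLE else len(doc.title) + 1
                etype = span.entity_type if span.entity_type != "UNSPECIFIED" else "CHEMICAL"
                ann_lines.append(
                    f"{doc.doc_id}\tT{k}\t{etype}\t{span.start + offset}\t"
                    f"{span.end + offset}\t{span.text}"
                )
    return "\n".join(abs_lines) + ("\n" if abs_lines else ""), "\n".join(ann_lines) + (
        "\n" if ann_lines else ""
    )


def merge_corpora(a: list[Document], b: list[Document]) -> list[Document]:
    """Concatenate two corpora, prefixing doc_ids ("a:", "b:") on collision."""
    ids_a = {d.doc_id for d in a}
    ids_b = {d.doc_id for d in b}
    collisions = ids_a & ids_b
    out: list[Document] = []
    for doc in a:
        if doc.doc_id in collisions:
            doc = doc.copy()
            doc.doc_id = f"a:{doc.doc_id}"
        out.append(doc)
    for doc in b:
        if doc.doc_id in collisions:
            doc = doc.copy()
            doc.doc_id = f"b:{doc.doc_id}"
        out.append(doc)
    return out
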