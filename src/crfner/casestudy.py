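"""Application pipelines: candidate-inhibitor extraction and literature-profile
differencing.

Candidate inhibitors: in a corpus of abstracts pre-selected for relevance to a
target (e.g. HIV reverse transcriptase inhibition), a predicted chemical
mention is a candidate inhibitor when its abstract also mentions at least one
protein/gene — the co-occurrence rule — after removing the FORMULA and FAMILY
surface classes (ions and compound families, which are never specific small-
molecule inhibitors).

Profile differencing: the unique normalized protein/gene names extracted from
two groups of abstracts (e.g. HIV elite-controller studies vs the general
HIV-positive literature) are compared as sets; names unique to the first group
are the disease-control-specific profile.  Name resolution against external
databases is an injectable interface with an offline file-backed stub, used to
flag extracted names that match no known protein (false-positive filtering).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .corpus_io import Document, EntitySpan
from .evaluation import normalize_name

__all__ = [
    "MISS",
    "NameProfile",
    "ProfileDiff",
    "filter_by_type",
    "select_candidate_inhibitors",
    "build_profile",
    "diff_profiles",
    "TsvResolver",
    "lookup_names",
    "subtract_groups",
]

logger = logging.getLogger(__name__)

#: Sentinel for a name the resolver could not associate with any record.
MISS = "MISS"

#: Surface classes excluded before inhibitor selection.
DEFAULT_EXCLUDED_TYPES = frozenset({"FORMULA", "FAMILY"})


@dataclass
class NameProfile:
    """Unique normalized entity names of one document group, with provenance."""

    group_id: str
    names: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class ProfileDiff:
    """Disjoint partition of two profiles' name inventories."""

    unique_to_a: set[str]
    unique_to_b: set[str]
    overlap: set[str]


def filter_by_type(
    entities: list[EntitySpan], excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TYPES
) -> list[EntitySpan]:
    """Drop entities whose entity_type is excluded (order preserved; idempotent)."""
    return [e for e in entities if e.entity_type not in excluded]


def select_candidate_inhibitors(doc: Document) -> set[str]:
    """Normalized names of the doc's predicted chemicals, under the
    co-occurrence rule: non-empty only if the doc also has >= 1 predicted
    protein/gene span.  Apply :func:`filter_by_type` to the predicted layer
    first when the FORMULA/FAMILY filter is wanted."""
    has_gene = any(e.entity_class == "GENE" for e in doc.predicted)
    chems = [e for e in doc.predicted if e.entity_class == "CHEMICAL"]
    if not has_gene or not chems:
        return set()
    return {normalize_name(e.text) for e in chems}


def extract_candidate_inhibitors(
    docs: list[Document], excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TYPES
) -> dict[str, set[str]]:
    """Per-document candidate sets: type filter then co-occurrence rule."""
    out: dict[str, set[str]] = {}
    for doc in docs:
        filtered = doc.copy()
        filtered.predicted = filter_by_type(doc.predicted, excluded)
        out[doc.doc_id] = select_candidate_inhibitors(filtered)
    return out


def build_profile(
    docs: list[Document], group_id: str, layer: str = "GENE", source: str = "predicted"
) -> NameProfile:
    """Collect the unique normalized names of one entity class across a group.

    ``source`` selects the predicted layer (the usual pipeline) or the gold
    annotations (for fixtures and audits).
    """
    if layer not in ("GENE", "CHEMICAL"):
        raise ValueError(f"bad layer {layer!r}")
    profile = NameProfile(group_id)
    for doc in docs:
        spans = doc.predicted if source == "predicted" else doc.entities
        for span in spans:
            if span.entity_class != layer:
                continue
            name = normalize_name(span.text)
            if not name:
                continue
            profile.names.add(name)
            profile.provenance.setdefault(name, set()).add(doc.doc_id)
    return profile


def diff_profiles(a: NameProfile, b: NameProfile) -> ProfileDiff:
    """Set difference of two name inventories: A-only, B-only, and overlap."""
    return ProfileDiff(
        unique_to_a=a.names - b.names,
        unique_to_b=b.names - a.names,
        overlap=a.names & b.names,
    )


def subtract_groups(group_a: list[Document], group_b: list[Document]) -> list[Document]:
    """Remove from group A any document also present (by doc_id) in group B.

    Applied upstream of profiling so the first group contains only abstracts
    exclusive to it.
    """
    ids_b = {d.doc_id for d in group_b}
    return [d for d in group_a if d.doc_id not in ids_b]


class TsvResolver:
    """Offline name resolver backed by a TSV of ``name<TAB>id<TAB>synonyms``.

    Synonyms are ';'-separated; lookup is over normalized surface forms of
    both primary names and synonyms.
    """

    def __init__(self, path):
        self.table: dict[str, dict] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or not row[0].strip():
                    continue
                name, ident = row[0], row[1] if len(row) > 1 else ""
                synonyms = row[2].split(";") if len(row) > 2 and row[2] else []
                record = {
                    "name": name,
                    "id": ident,
                    "synonyms": [s.strip() for s in synonyms if s.strip()],
                }
                for key in [name] + record["synonyms"]:
                    self.table.setdefault(normalize_name(key), record)

    def resolve(self, name: str):
        return self.table.get(normalize_name(name))


def lookup_names(names: set[str], resolver) -> dict[str, object]:
    """Map every name to its resolver record, or MISS.

    Names the resolver cannot associate with any record are the pipeline's
    false-positive candidates and are reported (but never dropped here).
    Resolver exceptions degrade to per-name MISS with a warning; the pipeline
    never aborts on lookup failure.
    """
    out: dict[str, object] = {}
    for name in sorted(names):
        try:
            record = resolver.resolve(name)
        except Exception as exc:  # noqa: BLE001 - external resolver boundary
            logger.warning("resolver failed for %r: %s", name, exc)
            record = None
        out[name] = record if record is not None else MISS
    misses = [n for n, r in out.items() if r is MISS]
    if misses:
        logger.info("%d names not associated with any record: %s", len(misses), misses)
    return out
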