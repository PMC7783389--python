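"""Generator of annotated abstract corpora with planted mentions.

The generator emulates the statistical structure the tagger relies on in the
real chemical / gene-protein corpora: documents (title + abstract) of filler
vocabulary with planted mentions whose surface shapes follow the seven
chemical mention classes and two gene-mention styles, character-offset
annotations that are always token-aligned and valid, and non-specific cue
words (the C/G lexicons) placed immediately before a mention with a
configurable probability.

Surface patterns per class are chosen so each class is separable by the
orthographic feature set (case, digits, symbols, suffixes, length): coined
lowercase names with drug-like suffixes (TRIVIAL), hyphen/digit nomenclature
(SYSTEMATIC), short all-caps tokens (ABBREVIATION), element-symbol/digit
strings (FORMULA), uppercase-dash-number codes (IDENTIFIER), coordinated
pairs (MULTIPLE), plural class nouns (FAMILY), and for genes, symbol+digit
tokens and "<name> protein"-style bigrams.  Mention *vocabularies* are random
per seed, so a model trained on one slice of a corpus must generalize to
unseen names on another slice — which is the property the feature scheme is
supposed to deliver.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .corpus_io import ABSTRACT, TITLE, CHEMICAL_TYPES, Document, EntitySpan

__all__ = ["SynthConfig", "generate_corpus", "generate_grouped_profiles"]

_CHEM_TYPES = tuple(sorted(CHEMICAL_TYPES))

_SYLLABLES = (
    "ba", "co", "da", "fe", "ga", "lu", "mi", "na", "pra", "ri", "sa", "te",
    "vi", "zo", "xen", "dor", "gan", "mer", "tol", "vin", "las", "pir", "quo",
)
_TRIVIAL_SUFFIXES = ("nib", "vir", "mab", "statin", "azole", "idine", "olol", "cillin")
_SYSTEMATIC_TAILS = ("phosphate", "carboxylate", "sulfonate", "acetate", "amine")
_FAMILY_SUFFIXES = ("oids", "ines", "ates")
_FAMILY_HEADS = ("hormones", "acids", "esters")
_MULTIPLE_PREFIX_PAIRS = (("tri", "di"), ("mono", "bis"), ("di", "tetra"))
_GENE_HEAD_SUFFIXES = ("ase", "in", "ogen")
_GENE_HEAD_NOUNS = ("protein", "receptor", "kinase")
_ELEMENTS = ("C", "H", "N", "O", "S", "P", "Cl", "Na", "K", "Ca", "Mg", "Br")


def _load_words(name: str) -> tuple[str, ...]:
    text = resources.files("crfner.data").joinpath(name).read_text(encoding="utf-8")
    return tuple(w.strip() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for corpus generation.

    Densities are expected mentions per document (Poisson); ``cue_rate`` is
    the probability that a mention is immediately preceded by a cue word from
    the matching non-specific-term lexicon; ``type_mix`` is the distribution
    over the seven chemical classes and must sum to 1.
    """

    n_docs: int = 100
    mean_tokens: int = 60
    chem_density: float = 3.0
    gene_density: float = 3.0
    type_mix: tuple[tuple[str, float], ...] = tuple((t, 1.0 / 7.0) for t in _CHEM_TYPES)
    cue_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chem_density < 0 or self.gene_density < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.cue_rate <= 1.0:
            raise ValueError("cue_rate must be in [0, 1]")
        probs = dict(self.type_mix)
        if set(probs) != set(_CHEM_TYPES):
            raise ValueError("type_mix must cover exactly the 7 chemical types")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")


def _stem(rng: np.random.Generator, n_syll: int = 2) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))


def _chem_mention(rng: np.random.Generator, ctype: str) -> list[str]:
    """Whitespace units of one chemical mention of the given class."""
    if ctype == "TRIVIAL":
        return [_stem(rng, int(rng.integers(2, 4))) + str(rng.choice(_TRIVIAL_SUFFIXES))]
    if ctype == "SYSTEMATIC":
        return [
            f"{_stem(rng)}-{int(rng.integers(1, 10))}-{rng.choice(_SYSTEMATIC_TAILS)}"
        ]
    if ctype == "ABBREVIATION":
        n = int(rng.integers(2, 6))
        return ["".join(chr(ord("A") + int(i)) for i in rng.integers(0, 26, n))]
    if ctype == "FORMULA":
        n = int(rng.integers(2, 5))
        parts = [
            str(rng.choice(_ELEMENTS)) + str(int(rng.integers(1, 13))) for _ in range(n)
        ]
        return ["".join(parts)]
    if ctype == "IDENTIFIER":
        letters = "".join(chr(ord("A") + int(i)) for i in rng.integers(0, 26, int(rng.integers(2, 5))))
        return [f"{letters}-{int(rng.integers(100, 1000))}"]
    if ctype == "MULTIPLE":
        a, b = _MULTIPLE_PREFIX_PAIRS[int(rng.integers(len(_MULTIPLE_PREFIX_PAIRS)))]
        tail = str(rng.choice(_SYSTEMATIC_TAILS))
        return [_stem(rng) + "oside", f"{a}-", "and", f"{b}-{tail}s"]
    if ctype == "FAMILY":
        if rng.random() < 0.5:
            return [_stem(rng, 2) + str(rng.choice(_FAMILY_SUFFIXES))]
        return [_stem(rng, 2) + "oid", str(rng.choice(_FAMILY_HEADS))]
    raise ValueError(f"unknown chemical type {ctype!r}")


def _gene_mention(rng: np.random.Generator) -> list[str]:
    u = rng.random()
    if u < 0.4:
        n = int(rng.integers(3, 6))
        sym = "".join(chr(ord("A") + int(i)) for i in rng.integers(0, 26, n))
        return [sym + str(int(rng.integers(1, 10)))]
    if u < 0.8:
        return [_stem(rng, 2) + str(rng.choice(_GENE_HEAD_SUFFIXES)), str(rng.choice(_GENE_HEAD_NOUNS))]
    # allele/locus style compound symbol, e.g. "HLA-B27"
    sym = "".join(chr(ord("A") + int(i)) for i in rng.integers(0, 26, int(rng.integers(2, 4))))
    tail = chr(ord("A") + int(rng.integers(0, 26))) + str(int(rng.integers(1, 100)))
    return [f"{sym}-{tail}"]


def _build_section(
    rng: np.random.Generator,
    fillers: tuple[str, ...],
    cues: dict[str, tuple[str, ...]],
    n_filler: int,
    mentions: list[tuple[str, str, list[str]]],
    cue_rate: float,
) -> tuple[str, list[tuple[int, int, str, str, str]]]:
    """Assemble one section; returns (text, [(start, end, text, class, type)])."""
    units: list[tuple[str, int]] = [(str(w), -1) for w in rng.choice(fillers, size=n_filler)]
    # Choose all insertion points on the filler-only list, then insert from the
    # highest position down: blocks can be adjacent but never interleave, so
    # planted spans never overlap.
    positions = [int(p) for p in rng.integers(0, n_filler + 1, size=len(mentions))]
    cue_draws = rng.random(len(mentions))
    order = sorted(range(len(mentions)), key=lambda i: positions[i], reverse=True)
    for m_idx in order:
        eclass, _etype, m_units = mentions[m_idx]
        block = [(u, m_idx) for u in m_units]
        if cue_draws[m_idx] < cue_rate:
            cue_pool = cues["C"] if eclass == "CHEMICAL" else cues["G"]
            block = [(str(rng.choice(cue_pool)), -1)] + block
        units[positions[m_idx] : positions[m_idx]] = block
    text_parts: list[str] = []
    cursor = 0
    extents: dict[int, list[int]] = {}
    for word, m_idx in units:
        if text_parts:
            cursor += 1  # single space joiner
        start = cursor
        cursor += len(word)
        text_parts.append(word)
        if m_idx >= 0:
            extents.setdefault(m_idx, [start, cursor])
            extents[m_idx][1] = cursor
    text = " ".join(text_parts)
    spans = []
    for m_idx, (eclass, etype, _units) in enumerate(mentions):
        if m_idx not in extents:
            continue
        start, end = extents[m_idx]
        spans.append((start, end, text[start:end], eclass, etype))
    spans.sort(key=lambda s: s[0])
    return text, spans


def generate_corpus(config: SynthConfig) -> list[Document]:
    """Generate a corpus of annotated documents; identical for identical seeds."""
    rng = np.random.default_rng(config.seed)
    fillers = _load_words("fillers.txt")
    cues = {"C": _load_words("chem_cues.txt"), "G": _load_words("gene_cues.txt")}
    types, probs = zip(*config.type_mix)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    docs: list[Document] = []
    for i in range(config.n_docs):
        mentions: list[tuple[str, str, list[str]]] = []
        for _ in range(int(rng.poisson(config.chem_density))):
            ctype = str(types[int(rng.choice(len(types), p=probs))])
            mentions.append(("CHEMICAL", ctype, _chem_mention(rng, ctype)))
        for _ in range(int(rng.poisson(config.gene_density))):
            gtype = "GENE-Y" if rng.random() < 0.5 else "GENE-N"
            mentions.append(("GENE", gtype, _gene_mention(rng)))
        # ~10% of mentions land in the (short) title
        title_mentions, abstract_mentions = [], []
        for m in mentions:
            (title_mentions if rng.random() < 0.1 else abstract_mentions).append(m)
        title_len = int(rng.integers(5, 10))
        abstract_len = max(15, int(rng.poisson(config.mean_tokens)))
        t_text, t_spans = _build_section(
            rng, fillers, cues, title_len, title_mentions, config.cue_rate
        )
        a_text, a_spans = _build_section(
            rng, fillers, cues, abstract_len, abstract_mentions, config.cue_rate
        )
        doc = Document(doc_id=f"SYN{i:05d}", title=t_text, abstract=a_text)
        for section, spans in ((TITLE, t_spans), (ABSTRACT, a_spans)):
            for start, end, text, eclass, etype in spans:
                doc.entities.append(
                    EntitySpan(
                        section=section,
                        start=start,
                        end=end,
                        text=text,
                        entity_class=eclass,
                        entity_type=etype,
                    )
                )
        doc.validate()
        docs.append(doc)
    return docs


def _unique_gene_names(rng: np.random.Generator, n: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        sym = "".join(chr(ord("A") + int(i)) for i in rng.integers(0, 26, int(rng.integers(3, 7))))
        name = sym + str(int(rng.integers(1, 100)))
        key = name.casefold()
        if key not in seen:
            seen.add(key)
            names.append(name)
    return names


def generate_grouped_profiles(
    size_a: int, size_b: int, overlap: int, seed: int = 0
) -> tuple[list[Document], list[Document]]:
    """Two document groups whose planted gene-name inventories have exactly
    the requested unique-name counts and overlap (on the gold layer)."""
    if overlap < 0 or overlap > min(size_a, size_b):
        raise ValueError(
            f"infeasible counts: overlap {overlap} vs sizes {size_a}, {size_b}"
        )
    rng = np.random.default_rng(seed)
    fillers = _load_words("fillers.txt")
    total = _unique_gene_names(rng, size_a + size_b - overlap)
    shared = total[:overlap]
    only_a = total[overlap : overlap + (size_a - overlap)]
    only_b = total[overlap + (size_a - overlap) :]

    def _docs(names: list[str], prefix: str) -> list[Document]:
        docs = []
        for d, i in enumerate(range(0, len(names), 5)):
            chunk = names[i : i + 5]
            units: list[tuple[str, bool]] = []
            for name in chunk:
                units.append((str(rng.choice(fillers)), False))
                units.append((name, True))
            units.append((str(rng.choice(fillers)), False))
            text = " ".join(u for u, _ in units)
            doc = Document(doc_id=f"{prefix}{d:05d}", title="synthetic group fixture", abstract=text)
            cursor = 0
            for k, (word, is_name) in enumerate(units):
                if k:
                    cursor += 1
                if is_name:
                    doc.entities.append(
                        EntitySpan(
                            section=ABSTRACT,
                            start=cursor,
                            end=cursor + len(word),
                            text=word,
                            entity_class="GENE",
                            entity_type="GENE-Y",
                        )
                    )
                cursor += len(word)
            doc.validate()
            docs.append(doc)
        return docs

    return _docs(shared + only_a, "A"), _docs(shared + only_b, "B")
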