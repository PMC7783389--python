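"""Per-token feature extraction and ±1-token context windows for the CRF.

Every token is described by a fixed set of orthographic and lexical
attributes — the word and its lowercase form, case and digit flags,
non-specific-term and stop-word membership, a symbol flag, 3- and 2-character
suffixes, the first character, the length, and a part-of-speech tag — plus
copies of the same attributes for the neighbouring token on each side under
``prev:`` / ``next:`` prefixes.  Sequence boundaries carry ``BOS`` / ``EOS``
flags instead of the missing neighbour block.

Non-specific terms are general cue words whose proximity signals a nearby
mention: a "C" lexicon for chemicals (e.g. "inhibit", "chemical") and a "G"
lexicon for genes/proteins (e.g. "target", "genes").  A term may carry both
marks, so membership is exposed as two separate booleans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

from .textprep import Token

__all__ = [
    "Lexicon",
    "load_lexicon",
    "default_lexicons",
    "rule_pos_tag",
    "token_features",
    "sequence_features",
]

logger = logging.getLogger(__name__)

FeatureMap = dict  # token attribute name -> str | bool | int


@dataclass(frozen=True)
class Lexicon:
    """A case-insensitive term list tagged C (chemical cue), G (gene cue) or STOP."""

    entries: frozenset[str]
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in ("C", "G", "STOP"):
            raise ValueError(f"bad lexicon tag {self.tag!r}")

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path, tag: str) -> Lexicon:
    """Read a one-term-per-line file into a lowercased, deduplicated Lexicon."""
    with open(path, encoding="utf-8") as fh:
        terms = frozenset(line.strip().lower() for line in fh if line.strip())
    if not terms:
        logger.warning("lexicon file %s is empty", path)
    return Lexicon(terms, tag)


def _packaged_lexicon(name: str, tag: str) -> Lexicon:
    text = resources.files("crfner.data").joinpath(name).read_text(encoding="utf-8")
    return Lexicon(frozenset(t.strip().lower() for t in text.splitlines() if t.strip()), tag)


def default_lexicons() -> list[Lexicon]:
    """The packaged C/G cue lists and English stop-word list.

    These are small curated seeds; real analyses may substitute larger,
    domain-tuned lists via :func:`load_lexicon`.
    """
    return [
        _packaged_lexicon("chem_cues.txt", "C"),
        _packaged_lexicon("gene_cues.txt", "G"),
        _packaged_lexicon("stopwords.txt", "STOP"),
    ]


# ---------------------------------------------------------------------------
# Default part-of-speech provider: a small deterministic rule tagger.
# Any callable list[str] -> list[str] over token texts may be substituted
# (e.g. a full Penn-treebank tagger); tags are treated as opaque strings.

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT", "these": "DT",
    "those": "DT", "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN",
    "for": "IN", "with": "IN", "from": "IN", "to": "TO", "and": "CC", "or": "CC",
    "but": "CC", "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "not": "RB", "we": "PRP", "it": "PRP", "they": "PRP", "as": "IN",
}

_SUFFIX_RULES = (
    ("ly", "RB"), ("ing", "VBG"), ("ed", "VBD"), ("tion", "NN"), ("ions", "NNS"),
    ("ity", "NN"), ("ies", "NNS"), ("s", "NNS"),
)


def rule_pos_tag(words: list[str]) -> list[str]:
    """Deterministic suffix/closed-class tagger used as the default POS provider."""
    tags = []
    for w in words:
        lw = w.lower()
        if lw in _CLOSED_CLASS:
            tags.append(_CLOSED_CLASS[lw])
        elif w.isdigit():
            tags.append("CD")
        elif not any(c.isalnum() for c in w):
            tags.append("SYM")
        elif w[:1].isupper() and lw not in _CLOSED_CLASS:
            tags.append("NNP")
        else:
            for suf, tag in _SUFFIX_RULES:
                if lw.endswith(suf) and len(lw) > len(suf) + 1:
                    tags.append(tag)
                    break
            else:
                tags.append("NN")
    return tags


# ---------------------------------------------------------------------------

_NON_WORD = re.compile(r"[^\w]", re.UNICODE)

_LENGTH_BUCKETS = ((1, "1"), (2, "2"), (3, "3"), (6, "4-6"), (10, "7-10"))


def _length_bucket(n: int) -> str:
    for hi, name in _LENGTH_BUCKETS:
        if n <= hi:
            return name
    return ">10"


def token_features(token: Token | str, postag: str, lexicons: list[Lexicon]) -> FeatureMap:
    """Compute the base attribute set for one token.

    Suffixes of words shorter than the window are the whole word.
    ``hassymbols`` is true iff the token contains a character that is neither
    alphanumeric nor underscore.
    """
    word = token.text if isinstance(token, Token) else token
    lower = word.lower()
    in_c = in_g = in_stop = False
    for lex in lexicons:
        if lower in lex.entries:
            if lex.tag == "C":
                in_c = True
            elif lex.tag == "G":
                in_g = True
            else:
                in_stop = True
    return {
        "word": word,
        "lower": lower,
        "isupper": word.isupper(),
        "istitle": word[:1].isupper(),
        "isdigit": word.isdigit(),
        "hasdigits": any(c.isdigit() for c in word),
        "isnonspecific_C": in_c,
        "isnonspecific_G": in_g,
        "isstopword": in_stop,
        "hassymbols": bool(_NON_WORD.search(word)),
        "suffix3": word[-3:],
        "suffix2": word[-2:],
        "firstchar": word[:1],
        "length": len(word),
        "length_bucket": _length_bucket(len(word)),
        "postag": postag,
    }


def sequence_features(
    tokens: list[Token],
    pos_provider=rule_pos_tag,
    lexicons: list[Lexicon] | None = None,
) -> list[FeatureMap]:
    """Base features per token plus neighbour copies under prev:/next: prefixes.

    The first element carries ``BOS``, the last ``EOS`` (a one-token sequence
    carries both and no neighbour blocks).
    """
    if lexicons is None:
        lexicons = default_lexicons()
    words = [t.text if isinstance(t, Token) else t for t in tokens]
    tags = pos_provider(words)
    if len(tags) != len(words):
        raise ValueError("POS provider returned wrong number of tags")
    base = [token_features(t, tag, lexicons) for t, tag in zip(tokens, tags)]
    out: list[FeatureMap] = []
    for i, feats in enumerate(base):
        fm = dict(feats)
        if i > 0:
            for k, v in base[i - 1].items():
                fm[f"prev:{k}"] = v
        else:
            fm["BOS"] = True
        if i < len(base) - 1:
            for k, v in base[i + 1].items():
                fm[f"next:{k}"] = v
        else:
            fm["EOS"] = True
        out.append(fm)
    return out
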