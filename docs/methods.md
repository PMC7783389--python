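# Methods

## Task and data model

The package extracts named entities of two classes — chemicals and
genes/proteins — from abstracts stored in standoff form: an abstracts table
(`doc_id`, title, abstract) and an annotations table of character-offset
spans. Two tab-separated dialects are read and written. In the
chemdner-style dialect offsets count within each section (title or abstract)
separately; in the chemprot-style dialect offsets count within the
concatenation `title + TAB + abstract`, and the reader assigns each span to a
section from its position. In both dialects the reader enforces
slice-equals-text for every span, so any offset-convention drift fails loudly
instead of corrupting data. Offsets are 0-based half-open and count Unicode
code points (the corpora contain Greek letters and typographic dashes).
Chemical mentions carry one of seven surface classes (ABBREVIATION, FAMILY,
FORMULA, IDENTIFIER, MULTIPLE, SYSTEMATIC, TRIVIAL); gene/protein mentions
carry GENE-Y (normalizable to a database record) or GENE-N. Predicted spans
may carry UNSPECIFIED where the fine type is unknown.

## Preprocessing

Tokenization is the word/punctuation rule (maximal runs of word characters,
or of non-word non-space characters), which is lossless given the source
text and splits hyphen/digit nomenclature into informative pieces
("sphingosine-1-phosphate" → 5 tokens). Spans are converted to per-token
SOBIE labels (Single/Out/Begin/Inside/End). Two conventions the corpora
leave open are fixed as follows:

* a span that starts or ends inside a token is snapped outward to whole
  tokens with a logged warning — this keeps the labeling total and favours
  recall;
* decoding of ill-formed label sequences from an imperfect tagger is
  lenient and deterministic: a stray I or E opens/closes a one-token entity,
  a B not followed by I/E closes as a one-token entity, and an entity still
  open at the sequence end is closed there. On well-formed sequences
  decoding inverts encoding exactly (property-tested).

## Features

Each token contributes a fixed attribute set: word, lowercase word,
uppercase/titlecase/digit flags, has-digits, has-symbols, membership in the
C (chemical-cue) and G (gene-cue) "non-specific term" lexicons, stop-word
membership, 3- and 2-character suffixes (the whole word when shorter), first
character, length, and a POS tag; plus copies of the neighbours' attributes
under `prev:`/`next:` prefixes and BOS/EOS flags at sequence boundaries.
Context windows never cross a section boundary. Design choices:

* The single "is non-specific" notion is exposed as two booleans
  (`isnonspecific_C`, `isnonspecific_G`) because a term may carry both
  marks and the two cue classes signal different entity classes.
* Length is emitted both as the raw integer and as a categorical bucket
  (1, 2, 3, 4–6, 7–10, >10); linear CRFs exploit categorical indicators
  better than a single monotone feature.
* POS tagging is an injectable provider (any callable from words to opaque
  tag strings). The default is a small deterministic rule tagger
  (closed-class word list + suffix rules); it keeps the package free of
  heavyweight model dependencies, and any Penn-tagset tagger can be
  substituted without retraining code changes (weights must be retrained,
  since tags are feature atoms).
* The shipped C/G cue lists and stop-word list are small curated seeds;
  serious use should substitute domain-tuned lists via `load_lexicon`.

## The CRF

A linear-chain CRF with indicator features: every `name=value` pair of a
token's feature map is an atom, hashed to an integer id at fit time; state
potentials are sums of atom weights per label, transitions are plain
label-pair weights (the common CRF-toolkit default; it also keeps the
enumeration oracle simple). Unseen atoms at prediction time are ignored.

Training maximizes `Σ [score(x,y) − log Z(x)] − c2‖w‖² − c1‖w‖₁` with
L-BFGS from a zero start, so fitting is deterministic given the data. The
likelihood gradient uses forward–backward marginals; the L1 term contributes
a subgradient (sign(w), 0 at 0). All recursions are in log space with
log-sum-exp stabilization; the forward/backward passes are vectorized across
sequences (padded to the longest sequence, with masks), which is what makes
hundreds of abstracts trainable in seconds on one core. Defaults:
c1 = c2 = 0.1, max 100 iterations, relative objective tolerance 1e−4. When
the iteration cap is reached first the model is still returned, flagged
`converged=False` with a warning. Hyperparameters can be grid-searched by
k-fold cross-validated macro-F1 (ties resolved toward the smallest (c1, c2)).

Viterbi ties are broken toward the earliest label in alphabet order at the
latest differing position; with all-zero weights the decoder therefore
returns the first alphabet label everywhere. Correctness is established in
the test suite by independent oracles: exhaustive enumeration of all label
sequences (T ≤ 6, |L| ≤ 5) for both the partition function and the Viterbi
path including its tie-break, closed-form gradients at the uniform model,
and central finite differences elsewhere.

## Models and composition

Span models (chemical, gene) are SOBIE taggers trained per entity class over
per-section sequences; they always carry the full five-label alphabet even
if a label is unobserved in training. The type model labels tokens inside
chemical mentions with the mention's class and O elsewhere. The combined
tagger runs the three models sequentially on a fresh document: chemical
spans are decoded, each typed by majority vote of the type model over its
tokens (tie → the earliest vote in token order; no non-O vote →
UNSPECIFIED), and gene spans are decoded independently. The two layers are
both kept even when they overlap — composition is deliberately not joint
inference, and keeping both layers maximizes downstream recall. Predictions
never mutate the input document; gold and predicted layers coexist.

Bundles (three models + lexicons + POS provider id) serialize to a single
JSON archive; floats round-trip exactly through shortest-repr decimal form,
so save → load → predict is byte-identical. Loading under different lexicons
is refused by hash comparison, because weights are meaningless if the
feature atoms change under them.

## Evaluation conventions

Token-label metrics are one-vs-rest per label with the zero-denominator
convention (a metric with an empty denominator is 0). The macro row is the
unweighted mean over all labels **including O** — this matches how per-label
SOBIE/type tables are conventionally averaged and is verified against the
published tables' own arithmetic in the acceptance tests. Entity-level
metrics require exact (document, section, start, end) agreement. The
document-level inhibitor protocol counts unique normalized names per
document: a recognized non-inhibitor is one FP, an unrecognized inhibitor
one FN. Name normalization is case-folding plus stripping flanking
punctuation; synonym merging is left to the resolver interface. Display
rounding is 4 decimals for per-label tables and 2 for document-level tables.

## Case-study pipelines

Candidate inhibitors: predicted chemical spans are filtered by surface class
(FORMULA and FAMILY removed — ions and compound families are not specific
small-molecule inhibitors), then the co-occurrence rule admits a document's
chemicals only if the document also carries at least one predicted
gene/protein span. Profile differencing: per group, the unique normalized
gene/protein names with per-name document provenance; the difference of two
profiles partitions names into A-only, B-only and overlap (count identities
are property-tested). When one group may contain the other's documents, the
shared documents are removed by doc-id subtraction before profiling.
External name resolution (e.g. against a protein database) is an injectable
interface with an offline TSV-backed stub; unresolvable names are reported
as MISS — the false-positive filter — and resolver failures degrade to MISS
rather than aborting the pipeline. Live database queries are out of scope.

## Synthetic corpus

The generator emulates the structure the tagger relies on in real corpora:
documents of filler vocabulary with planted, always token-aligned mentions;
each chemical class has a distinct surface pattern (drug-like lowercase
suffixes, hyphen/digit nomenclature, short all-caps, element-symbol/digit
strings, letters-dash-number codes, coordinated pairs, plural class nouns),
genes appear as symbol+digit tokens, "<name> protein"-style bigrams, and
dashed allele-style symbols; C/G cue words precede a mention with
probability `cue_rate`. Defaults — 60 mean abstract tokens, 3 expected
chemical and 3 expected gene mentions per document, uniform type mix,
cue rate 0.5 — were chosen once as plausible abstract-scale conditions.
Mention vocabularies are random per seed, so held-out evaluation measures
generalization of the feature scheme to unseen names, not memorization.

What passing on synthetic data does **not** show: real abstracts have far
richer filler language, nested and ambiguous mentions, inconsistent
annotation conventions, and heavy class imbalance, so the synthetic F1
values (≈0.93–0.99) are an upper bound on, not an estimate of, real-corpus
performance; real-corpus macro-F1 for taggers of this family is typically in
the 0.80–0.90 range. The grouped-profile generator plants gene-name
inventories with exact requested sizes and overlap, giving a fixture whose
profile-difference counts are known by construction.

## Problem sizes and limitations

The test suite and the acceptance script train on 400 generated documents
and evaluate on 100 (seed 42 in the tests), cross-validate with k = 5 on the
100-document default corpus, and check the CRF oracles on 100 random small
instances — sizes chosen so the whole pipeline, including training, runs on
a single core in minutes. Known limitations: no joint chemical/gene
inference; transitions are not feature-conjoined; the L1 subgradient
treatment does not produce exactly-sparse weights (an orthant-wise method
would); the rule POS tagger is crude (tags contribute little beyond suffix
features); and the resolver stub does no fuzzy matching.
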