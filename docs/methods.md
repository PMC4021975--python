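# Methods

This note documents the models and procedures implemented in `pgntag`,
the choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Data model and formats

Annotations are character spans with their surface strings, canonically
0-based, half-open, whitespace counted, with code points as the unit (so
Greek characters count as one position). The gene-list standoff layout
(`ID | start end | surface`) is read and written byte-exactly for ASCII
input. Some gene-list distributions count offsets over non-whitespace
characters with both ends inclusive; that convention is supported as a
reader/writer dialect with lossless conversion at the boundary, because a
single internal convention keeps every downstream computation simple.
Which convention a given external corpus actually uses cannot be settled
from a printed record alone, so neither dialect is asserted as "the"
standard; loaders take it as manifest metadata. An inline-XML writer is
provided for interoperability only; standoff files are the system of
record.

## Alias normalization

The alias key of a term is computed by, in order: trim and collapse
whitespace; map `-` and `/` to a single space; collapse again; lowercase
the first character; strip one trailing `s` from the final token when
that token has ≥4 characters, is not all-uppercase in its original
casing, and does not end in `ss`. The `ss` guard is ours: without it the
map is not idempotent (`basss → bass → bas`), and idempotence is what
makes index keys stable under re-normalization. The all-uppercase test
uses the token's casing *before* the initial-character lowercasing so
acronym plurals (`RASS`) are left alone. Only these three kinds of
variability are neutralized — no edit-distance matching — because
morphological variability is specific enough to compare PGN terms without
the false matches a generic string distance would admit.

Tokenization for dictionary scanning treats `-` and `/` as token
boundaries in alias mode and as in-token characters in exact mode; this
is what lets separator variants align while exact mode stays strict.
Left-most longest match is the default (right-most available by flag).
The frequency filter is applied after tagging; an equivalent lexicon
pre-filter is provided as an optimization and tested to give identical
output. Whether the original frequency comparison was case-folded is not
documented anywhere we could rely on; we case-fold by default and expose
a flag.

A note on the exact ⊆ alias containment property: it is guaranteed for
any fixed span, but left-most-longest *scanning* can in principle let an
alias-only longer match shadow a shorter exact match (lexicon
`{"Y", "X/Y"}` on text `"X Y"`). The generated corpora cannot produce
such shadowing, and the property is asserted there; it is an empirical
property of realistic lexica, not a theorem.

## Sequence tagger

The feature template per token: all character n-grams for n = 2–4;
starts/ends-with-capital and all-capitals flags; length buckets (1, 2,
3–5); digit flags read literally as *exactly one*, *exactly two*, *all
digits* (a token with three digits and a letter sets none); contains
punctuation (any non-alphanumeric, non-space code point); contains a
Greek-block character; plus the lowercased token itself. Each position
additionally receives its neighbours' features at offsets −2…+2, with an
edge marker outside the sequence.

The chain model is an averaged structured perceptron over {B, I, O} with
Viterbi decoding — a linear-chain discriminative model trained by
error-driven updates whose averaged weights damp oscillation on small
corpora. Training is deterministic under (corpus, config, seed); epochs
default to 8 with a seeded shuffle. Mention boundaries that split a token
snap outward to the covering token with a logged warning; overlapping
gold mentions resolve to the longer one. BIO decoding treats an orphan
`I` as the start of a mention. Tokenizer and nested-mention policy are
fixed here by decision; nothing in the upstream feature description
dictates them.

FP filtering keeps a dictionary annotation only when a model annotation
confirms it; the default policy is span *overlap* because lexical and
learned boundaries rarely agree to the character, and boundary
variability is exactly what the soft evaluation mode exists for.

## Evaluation

idf(t) = ln(D / d_t) with d_t = 0.5 for unseen tokens; tokens present in
every background document get weight exactly 0, which is what makes
ubiquitous tokens ("the", "protein") ignorable in cos98 matching. The
threshold comparison is strict (> 0.98) and configurable. cos98
candidates must additionally overlap positionally by default — without
that constraint identical surfaces anywhere in a document would
cross-match; the flag is exposed. Pairing is greedy, best similarity
first, ties broken by preferring identical spans and then by (gold start,
prediction start); the identical-span preference guarantees soft matching
never undercuts exact matching at equal similarity. Greedy was chosen
over optimal assignment for transparency; tests show it agrees with a
brute-force maximum matching on ≥99% of small random instances, and the
committed behaviour is the greedy one.

Alternative-annotation credit is this package's explicit interpretation
of a mechanism whose published description does not fully define the two
credit tiers: `tier1` re-credits a false positive matching an alternative
of a gene whose main annotation was matched; `tier1+tier2` additionally
credits alternatives of missed genes and cancels their false negatives.
Tier-1 rescues are committed before tier-2 rescues, so the tier-2 policy
credits a superset and the three policies are monotone in both precision
and recall by construction. The record identifier grouping alternatives
with their main annotation is the annotation's id field, as in
sentence-level gene lists where each record carries one gene.

## Error profiles

Profiles hold the top-N (default 100) error surfaces, descending by
count with lexicographic tie-break, case-preserved ("Ras" and "RAS" are
distinct naming events; case-folding is a flag). Vectors are aligned over
the union of the two profiles' surfaces with absent keys at 0 — the
union-per-comparison choice is flagged as one of two defensible readings
of profile construction. A constant aligned vector makes Pearson r
undefined; that is reported as a distinct no-variance outcome, never
silently 0. Clustering is agglomerative with complete linkage maintained
through the Lance–Williams recurrence (α₁ = α₂ = ½, β = 0, γ = ½) on
distance d = 1 − r (the correlation-to-distance transform is our choice),
with deterministic min-distance, min-index merges; tests verify the
heights against both a from-scratch maximal-distance oracle and scipy's
implementation.

Categorization, published as a manual curation, is made reproducible
here as a deterministic rule cascade over configurable term lists
(packaged defaults cover the documented example assignments): single and
double alphanumeric characters → 1C/2C; a single general-English token
not in the lexicon → GE; a whole-surface lexicon match → a-PG when short
(≤6 characters, digits, or internal capitals) else PGT; a
lexicon-matching prefix with trailing head nouns → ea-PG, with other
trailing tokens → xa-PG; then the biomedical-term list or a
biomedical-looking shape → BMT; else UNK, an artifact-only fallback
excluded from the Core/Margin/Artefact rollup. Assignments outside the
packaged examples reflect this cascade, not any curator's judgment.

## Synthetic data

The generator emulates the structure the pipeline needs to be testable:
a lexicon split between acronym-style short forms (`Kafo-7`) and
modifier-plus-head long forms; a Zipf-distributed background vocabulary
(exponent 1.1 by default, the classic near-1 shape of word-frequency
lists) whose top ranks are function words and head nouns with document
frequency equal to the corpus size (IDF 0); planted ambiguous lexicon
terms ranked strictly above the reference term `insulin` so the frequency
filter provably removes exactly their hits; and corpora whose sentences
come from fixed mention and distractor templates with constant ±2-token
windows, making the distractor/mention distinction learnable by the
sequence tagger in principle — which is what turns the FP-filter
precision claim into a testable property.

Per mention, the surface is a verbatim lexicon term with probability
c·(1−v), an alias variant with probability c·v (variants are generated
exactly by inverting the normalization rules, so alias-mode recall of
covered mentions is 1 by construction), or a novel out-of-lexicon term
with probability 1−c; a distractor accompanies each mention with
probability a. This yields closed forms: exact recall c·(1−v), alias
recall c, precision E[TP]/(E[TP]+a), and precision 1 after frequency
filtering. Gold mentions are drawn from the unambiguous pool, so the
filter's recall cost is zero by design; the ambiguous terms model
dictionary noise, not annotated mentions. Out-of-lexicon and distractor
surfaces recur with Zipf weights so that error profiles carry count
structure. The study defaults (30–200 documents, 4–10 mentions per
document, lexicon sizes 150–400, c = 0.8, v = 0.25, a = 0.2 giving
expected exact-mode precision 0.75) are the conditions under which all
reported quantities are computed.

What the generator does *not* emulate: real gene nomenclature, Medline
token distributions, topic differences between corpora, annotation-
guideline idiosyncrasies, or discontinuous/nested mentions. Passing tests
therefore demonstrate that the algorithms implement their definitions and
that the planted statistical structure is recovered — not that any
particular performance level transfers to real corpora.

## Known limitations

- The sequence tagger is a perceptron-trained linear chain; it matches
  the feature template and determinism contracts but will not reproduce
  the exact decision boundaries of any specific published CRF system.
- Greedy matching is committed behaviour even where a maximum matching
  would differ (rare, logged by the oracle test).
- The categorization cascade's BMT/GE boundary encodes list membership
  and surface shape, not semantics.
- No significance testing on profile correlations; no nestedness or
  other flexible-matching variants beyond cos98.
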