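"""Synthetic lexica, background frequency lists and annotated corpora.

Every pipeline stage is exercised on generated data with known ground
truth: a lexicon with controlled term-variant structure (separator /
initial-capitalization / plural variants invertible by alias matching), a
Zipf-distributed background vocabulary supplying the general-English
frequency list and IDF table, and corpora with mentions planted at
configured coverage, variant and out-of-vocabulary rates plus ambiguous
distractor terms planted as non-mentions.

Because the planting scheme is explicit, dictionary-tagging performance
has closed forms (:func:`expected_dictionary_metrics`):

* exact-mode recall  = coverage · (1 − variant_rate)
* alias-mode recall  = coverage
* precision          = E[TP] / (E[TP] + E[distractor hits]), with one
  distractor planted per mention with probability ``ambiguity_rate``

Mention sentences and distractor sentences use distinct context templates
whose ±2-token windows are constant, so a sequence tagger can in
principle learn to reject distractors from context — which is what makes
the false-positive-filter benefit testable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Set, Tuple

import numpy as np

from .model import AnnotatedCorpus, Annotation, Document, FrequencyList, Lexicon

FUNCTION_WORDS = (
    "the of and in to a was were for with is that on by at from as this are be".split()
)

_MENTION_TEMPLATES = (
    ("analysis showed that", "was upregulated in {f} samples"),
    ("expression levels of", "were measured across {f} tissues"),
    ("we observed that", "interacts directly with {f} components"),
    ("the results confirmed", "as a regulator of {f} signalling"),
)

_DISTRACTOR_TEMPLATES = (
    ("samples were stored in", "buffer during {f} preparation"),
    ("aliquots were diluted in", "solution before {f} analysis"),
    ("plates were washed with", "reagent at {f} concentration"),
)

_HEAD_NOUNS = ("protein", "gene", "family", "receptor")

_LONG_HEADS = ("kinase", "factor", "ligase", "cyclase", "peptide", "enzyme")

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"

# words with a fixed role in templates or resources; never generated
_RESERVED: Set[str] = (
    set(FUNCTION_WORDS)
    | set(_HEAD_NOUNS)
    | set(_LONG_HEADS)
    | {
        w
        for group in (_MENTION_TEMPLATES, _DISTRACTOR_TEMPLATES)
        for pre, post in group
        for w in (pre + " " + post).replace("{f}", "").split()
    }
    | {"insulin"}
)


@dataclass
class SynthConfig:
    """Knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    n_docs: int = 50
    sentences_per_doc: int = 3          # filler sentences per document
    mentions_per_doc_mean: float = 10.0
    lexicon_size: int = 500
    coverage: float = 0.8               # P(mention surface is an in-lexicon term)
    variant_rate: float = 0.25          # P(covered mention is an alias variant)
    ambiguity_rate: float = 0.2         # P(a distractor accompanies a mention)
    zipf_exponent: float = 1.1
    head_noun_rate: float = 0.0         # P(gold span extends over a head noun)
    short_long_ratio: float = 0.5       # share of acronym-style lexicon terms
    background_vocab: int = 2000
    background_docs: int = 1000
    reference_term: str = "insulin"
    generate_alternatives: bool = False
    oov_pool_size: int = 30             # distinct novel terms per corpus

    def __post_init__(self) -> None:
        for name in ("coverage", "variant_rate", "ambiguity_rate",
                     "head_noun_rate", "short_long_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.background_vocab < 100:
            raise ValueError("background vocabulary must have at least 100 terms")

    @property
    def oov_rate(self) -> float:
        return 1.0 - self.coverage


@dataclass(frozen=True)
class ProvenanceLabel:
    """Ground-truth origin of one planted span (never shown to taggers)."""

    doc_id: str
    start: int
    end: int
    surface: str
    label: Literal["verbatim", "variant", "oov", "ambiguous-term", "general-english"]


@dataclass
class GeneratedLexicon:
    lexicon: Lexicon
    short_terms: List[str]
    long_terms: List[str]
    ambiguous_terms: List[str]  # lexicon terms colliding with general English

    @property
    def mention_pool(self) -> List[str]:
        """Terms eligible as gold mentions (the unambiguous ones)."""
        amb = set(self.ambiguous_terms)
        return [t for t in self.short_terms + self.long_terms if t not in amb]


@dataclass
class GeneratedBackground:
    freq: FrequencyList
    vocabulary: List[str]       # rank order, most frequent first
    filler_words: List[str]     # sampling pool for sentence filler
    filler_probs: np.ndarray
    reference_rank: int


def _word(rng: np.random.Generator, n_syll: int = 3) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syll)
    )


def _unique_words(rng: np.random.Generator, n: int, taken: Set[str],
                  n_syll: int = 3) -> List[str]:
    out: List[str] = []
    while len(out) < n:
        w = _word(rng, n_syll)
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def gen_lexicon(config: SynthConfig) -> GeneratedLexicon:
    """Concept-per-term lexicon with acronym-style and long-form populations.

    Short forms look like ``Kfa-7`` (capitalised letter block, separator,
    digits); long forms are ``modifier head`` compositions.  A deterministic
    ``round(ambiguity_rate · lexicon_size)`` of the terms are single
    general-English-looking words that the background vocabulary will also
    contain — the planted lexical ambiguity.
    """
    if config.lexicon_size < 1:
        raise ValueError("lexicon_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_amb = int(round(config.ambiguity_rate * config.lexicon_size))
    n_amb = min(n_amb, config.lexicon_size)
    n_rest = config.lexicon_size - n_amb
    n_short = int(round(config.short_long_ratio * n_rest))
    n_long = n_rest - n_short

    taken: Set[str] = set(_RESERVED)
    short_terms = []
    blocks = _unique_words(rng, n_short, taken, n_syll=2)
    for i, block in enumerate(blocks):
        short_terms.append(f"{block.capitalize()}-{i + 1}")

    long_terms = []
    modifiers = _unique_words(rng, max(n_long, 1), taken, n_syll=3)
    for i in range(n_long):
        long_terms.append(f"{modifiers[i]} {_LONG_HEADS[i % len(_LONG_HEADS)]}")

    ambiguous = []
    while len(ambiguous) < n_amb:
        w = _word(rng, 3)
        if w not in taken and not w.endswith("s"):
            taken.add(w)
            ambiguous.append(w)

    entries = {}
    for i, term in enumerate(short_terms + long_terms + ambiguous):
        entries[f"C{i:05d}"] = {term}
    return GeneratedLexicon(
        lexicon=Lexicon(name=f"synth-lex-{config.seed}", entries=entries),
        short_terms=short_terms,
        long_terms=long_terms,
        ambiguous_terms=ambiguous,
    )


def gen_background(config: SynthConfig, lex: GeneratedLexicon) -> GeneratedBackground:
    """Zipf-distributed background frequency list with document frequencies.

    Rank order: function words first, then the lexicon's ambiguous terms
    (so their rate strictly exceeds the reference term's), then the
    reference term, then generic filler vocabulary.  Counts follow
    ``round(scale / rank^s)``; document frequencies scale with counts and
    saturate at the background document count, so ubiquitous words get
    IDF 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    taken = set(_RESERVED) | set(lex.ambiguous_terms) | {config.reference_term}
    n_filler = max(config.background_vocab - len(taken), 100)
    filler = _unique_words(rng, n_filler, taken, n_syll=3)
    ubiquitous = list(FUNCTION_WORDS) + list(_HEAD_NOUNS)
    vocabulary = (
        ubiquitous
        + [t.casefold() for t in lex.ambiguous_terms]
        + [config.reference_term]
        + filler
    )
    reference_rank = len(ubiquitous) + len(lex.ambiguous_terms) + 1
    scale = 1.0e7
    counts = {}
    doc_freqs = {}
    for rank, term in enumerate(vocabulary, start=1):
        c = max(1, int(round(scale / rank ** config.zipf_exponent)))
        counts[term] = c
        # function words and head nouns occur in essentially every abstract
        if term in ubiquitous:
            doc_freqs[term] = config.background_docs
        else:
            doc_freqs[term] = max(1, min(config.background_docs,
                                         int(round(config.background_docs * c / scale))))
    freq = FrequencyList(counts=counts, doc_freqs=doc_freqs,
                         n_docs=config.background_docs)
    filler_counts = np.array([counts[w] for w in filler], dtype=float)
    return GeneratedBackground(
        freq=freq,
        vocabulary=vocabulary,
        filler_words=filler,
        filler_probs=filler_counts / filler_counts.sum(),
        reference_rank=reference_rank,
    )


def alias_variants(term: str) -> List[str]:
    """Surface variants that alias-normalize to the same key as ``term``.

    Exactly the inverse of the alias rules: separator re-rendering
    (``-``/``/``/space), initial-capitalization toggle, and a plural "s"
    when the final token supports it.  The term itself is excluded.
    """
    out: Set[str] = set()
    for sep in (" ", "-", "/"):
        for orig in (" ", "-", "/"):
            if orig in term:
                out.add(term.replace(orig, sep))
    first = term[:1]
    base_forms = set(out) | {term}
    for form in list(base_forms):
        if first.isalpha():
            toggled = (first.lower() if first.isupper() else first.upper()) + form[1:]
            out.add(toggled)
    for form in list(out | {term}):
        last = form.split()[-1].replace("-", " ").replace("/", " ").split()[-1]
        if (len(last) >= 3 and not last.endswith("s")
                and not last.isupper() and last.isalpha()):
            out.add(form + "s")
    out.discard(term)
    return sorted(out)


def _zipf_weights(n: int, s: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def _fillers(rng: np.random.Generator, bg: GeneratedBackground, n: int) -> List[str]:
    idx = rng.choice(len(bg.filler_words), size=n, p=bg.filler_probs)
    return [bg.filler_words[i] for i in idx]


def _fill_template(template: str, rng: np.random.Generator,
                   bg: GeneratedBackground) -> str:
    while "{f}" in template:
        template = template.replace("{f}", _fillers(rng, bg, 1)[0], 1)
    return template


@dataclass
class GeneratedCorpus:
    corpus: AnnotatedCorpus
    provenance: List[ProvenanceLabel]


def gen_corpus(
    config: SynthConfig,
    lex: GeneratedLexicon,
    bg: GeneratedBackground,
    name: Optional[str] = None,
    extra_distractor_terms: Sequence[str] = (),
    mention_pool: Optional[Sequence[str]] = None,
) -> GeneratedCorpus:
    """Documents with planted gold mentions, distractors and filler.

    Per document the mention count is Poisson(``mentions_per_doc_mean``);
    each mention is verbatim, alias-variant or a novel out-of-lexicon term
    per the configured rates, and with probability ``ambiguity_rate``
    drags in one distractor sentence using an ambiguous term (or a term
    from ``extra_distractor_terms`` when given).  With
    ``head_noun_rate`` > 0 gold spans extend over an appended head noun;
    with ``generate_alternatives`` every multi-token gold mention also
    emits BC2-style sub-span alternatives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    pool = list(mention_pool) if mention_pool is not None else lex.mention_pool
    if not pool:
        raise ValueError("empty mention pool")
    distractor_pool = list(extra_distractor_terms) or list(lex.ambiguous_terms)
    if config.ambiguity_rate > 0 and not distractor_pool:
        raise ValueError("ambiguity_rate > 0 requires distractor terms")
    # distractor terms and novel terms recur with Zipf weights, so error
    # profiles carry count structure rather than flat one-off surfaces
    d_w = _zipf_weights(len(distractor_pool)) if distractor_pool else None
    oov_pool = [
        f"{w.capitalize()}-{i + 1}x"
        for i, w in enumerate(
            _unique_words(rng, config.oov_pool_size, set(_RESERVED), n_syll=2)
        )
    ]
    oov_w = _zipf_weights(len(oov_pool))

    documents: List[Document] = []
    gold: List[Annotation] = []
    alternatives: List[Annotation] = []
    provenance: List[ProvenanceLabel] = []

    for d in range(config.n_docs):
        doc_id = f"D{d:04d}"
        n_mentions = int(rng.poisson(config.mentions_per_doc_mean))
        pieces: List[Tuple[str, Optional[dict]]] = []

        for _ in range(n_mentions):
            u = rng.random()
            if u < config.coverage * (1.0 - config.variant_rate):
                term = pool[rng.integers(len(pool))]
                surface, label = term, "verbatim"
            elif u < config.coverage:
                term = pool[rng.integers(len(pool))]
                variants = alias_variants(term)
                surface = variants[rng.integers(len(variants))]
                label = "variant"
            else:
                surface = oov_pool[rng.choice(len(oov_pool), p=oov_w)]
                label = "oov"
            info = {"surface": surface, "label": label, "extended": False}
            if config.head_noun_rate > 0 and rng.random() < config.head_noun_rate:
                info["extended"] = True
                info["head"] = _HEAD_NOUNS[rng.integers(len(_HEAD_NOUNS))]
            t = _MENTION_TEMPLATES[rng.integers(len(_MENTION_TEMPLATES))]
            pieces.append((t, info))
            if rng.random() < config.ambiguity_rate:
                dterm = distractor_pool[rng.choice(len(distractor_pool), p=d_w)]
                dt = _DISTRACTOR_TEMPLATES[rng.integers(len(_DISTRACTOR_TEMPLATES))]
                pieces.append((dt, {"surface": dterm, "label": "distractor"}))

        for _ in range(config.sentences_per_doc):
            pieces.append((None, None))

        order = rng.permutation(len(pieces))
        text_parts: List[str] = []
        cursor = 0
        for k in order:
            template, info = pieces[k]
            if template is None:
                sentence = " ".join(_fillers(rng, bg, 5)) + "."
                planted = None
            else:
                prefix = _fill_template(template[0], rng, bg)
                suffix = _fill_template(template[1], rng, bg)
                mention = info["surface"]
                if info.get("extended"):
                    mention_full = f"{mention} {info['head']}"
                else:
                    mention_full = mention
                sentence = f"{prefix} {mention_full} {suffix}."
                m_start = cursor + len(prefix) + 1
                planted = (m_start, m_start + len(mention_full), mention_full, info)
            text_parts.append(sentence)
            if planted is not None:
                start, end, mention_full, info = planted
                if info["label"] == "distractor":
                    provenance.append(ProvenanceLabel(
                        doc_id, start, end, mention_full, "ambiguous-term"))
                else:
                    ann = Annotation(doc_id=doc_id, start=start, end=end,
                                     surface=mention_full, source="gold")
                    gold.append(ann)
                    provenance.append(ProvenanceLabel(
                        doc_id, start, end, mention_full, info["label"]))
                    if config.generate_alternatives:
                        alternatives.extend(_sub_span_alternatives(ann))
            cursor += len(sentence) + 1
        documents.append(Document(doc_id=doc_id, text=" ".join(text_parts)))

    corpus = AnnotatedCorpus(
        name=name or f"synth-corpus-{config.seed}",
        documents=documents,
        gold=gold,
        alternatives=alternatives,
    )
    for ann in gold:
        assert corpus.texts[ann.doc_id][ann.start:ann.end] == ann.surface
    return GeneratedCorpus(corpus=corpus, provenance=provenance)


def _sub_span_alternatives(ann: Annotation) -> List[Annotation]:
    """BC2-style alternatives: token sub-spans of a multi-token mention."""
    words = ann.surface.split(" ")
    if len(words) < 2:
        return []
    alts = []
    # drop the last token, and drop the first token
    head_len = len(words[0])
    alts.append(Annotation(
        doc_id=ann.doc_id, start=ann.start,
        end=ann.start + len(ann.surface) - len(words[-1]) - 1,
        surface=" ".join(words[:-1]), source="alt"))
    alts.append(Annotation(
        doc_id=ann.doc_id, start=ann.start + head_len + 1, end=ann.end,
        surface=" ".join(words[1:]), source="alt"))
    return alts


@dataclass(frozen=True)
class ExpectedMetrics:
    precision: float
    recall: float


def expected_dictionary_metrics(
    config: SynthConfig,
) -> Dict[Tuple[str, bool], ExpectedMetrics]:
    """Closed-form expected (P, R) of dictionary tagging on generated corpora.

    Keyed by (mode, frequency_filtered).  Derivation: per planted mention,
    the surface is a verbatim lexicon term w.p. ``c(1−v)`` (matched in both
    modes), an alias variant w.p. ``cv`` (matched in alias mode only), or
    out-of-lexicon w.p. ``1−c`` (never matched); independently one
    distractor is planted w.p. ``a`` and is always matched (it is a
    verbatim lexicon term).  Gold mentions never use ambiguous terms, so
    the frequency filter removes exactly the distractor hits.
    """
    c, v, a = config.coverage, config.variant_rate, config.ambiguity_rate
    out = {}
    for mode, tp_rate in (("exact", c * (1.0 - v)), ("alias", c)):
        p_unf = tp_rate / (tp_rate + a) if (tp_rate + a) > 0 else 1.0
        out[(mode, False)] = ExpectedMetrics(precision=p_unf, recall=tp_rate)
        out[(mode, True)] = ExpectedMetrics(precision=1.0 if tp_rate > 0 else 0.0,
                                            recall=tp_rate)
    return out
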