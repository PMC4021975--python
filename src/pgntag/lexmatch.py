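"""Dictionary tagging with morphological alias matching.

Gene and protein names vary morphologically in text far more than they do
in nomenclature databases: separators shift ("HZF-7" / "HZF 7" / "HZF/7"),
sentence position capitalises the first letter, and plural forms add a
trailing "s".  Alias matching neutralises exactly these three kinds of
variability — nothing fuzzier — which keeps dictionary lookups specific
while recovering the common surface variants.

The module provides term normalization (:func:`normalize_term`), indexed
dictionary tagging with left-most (or right-most) longest match
(:func:`dictionary_tag`), a background-frequency disambiguation filter that
drops terms more common in general English than a reference term
(:func:`frequency_filter`), and lexicon-vs-lexicon cross-tagging
(:func:`cross_tag`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Literal, Sequence, Set, Tuple

from .model import Annotation, Document, FrequencyList, Lexicon

Mode = Literal["exact", "alias"]

# alias mode: separators are token boundaries; exact mode: in-token chars
_ALIAS_TOKEN_RE = re.compile(r"[0-9A-Za-zͰ-Ͽ]+")
_EXACT_TOKEN_RE = re.compile(r"[0-9A-Za-zͰ-Ͽ/-]+")


@dataclass
class AliasRules:
    """Configurable pieces of alias normalization."""

    separators: str = "-/"
    lower_initial: bool = True
    strip_plural: bool = True
    min_plural_len: int = 4


def normalize_term(term: str, mode: Mode, rules: AliasRules | None = None) -> str:
    """Normalize a term for index keys and lookups.

    exact mode: trim and collapse internal whitespace, nothing else.

    alias mode, in order: trim; map each separator character (``-`` and
    ``/``) to a single space; collapse whitespace; lowercase the first
    character; strip one trailing "s" from the final token when that token
    has at least 4 characters, is not all-uppercase in its original casing,
    and does not end in "ss" (the last guard keeps the map idempotent).
    """
    rules = rules or AliasRules()
    stripped = term.strip()
    if not stripped:
        raise ValueError("empty or whitespace-only term")
    collapsed = " ".join(stripped.split())
    if mode == "exact":
        return collapsed
    for sep in rules.separators:
        collapsed = collapsed.replace(sep, " ")
    collapsed = " ".join(collapsed.split())
    if not collapsed:
        raise ValueError(f"term {term!r} normalizes to nothing in alias mode")
    original_last = collapsed.split()[-1]
    if rules.lower_initial:
        collapsed = collapsed[0].lower() + collapsed[1:]
    if rules.strip_plural:
        tokens = collapsed.split()
        last = tokens[-1]
        if (
            last.endswith("s")
            and not last.endswith("ss")
            and len(last) >= rules.min_plural_len
            and not original_last.isupper()
        ):
            tokens[-1] = last[:-1]
            collapsed = " ".join(tokens)
    return collapsed


@dataclass
class TermIndex:
    """Normalized-key lookup table over a lexicon.

    ``index`` maps each normalized key to the set of (concept_id, original
    term) pairs that produce it; ``max_term_tokens`` bounds the window the
    document scanner needs to consider.
    """

    mode: Mode
    index: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    max_term_tokens: int = 0
    rules: AliasRules = field(default_factory=AliasRules)

    def lookup(self, surface: str) -> Set[Tuple[str, str]]:
        try:
            key = normalize_term(surface, self.mode, self.rules)
        except ValueError:
            return set()
        return self.index.get(key, set())

    def token_re(self) -> re.Pattern:
        return _ALIAS_TOKEN_RE if self.mode == "alias" else _EXACT_TOKEN_RE


def build_index(lexicon: Lexicon, mode: Mode, rules: AliasRules | None = None) -> TermIndex:
    rules = rules or AliasRules()
    idx = TermIndex(mode=mode, rules=rules)
    token_re = idx.token_re()
    for cid, term in lexicon.items():
        key = normalize_term(term, mode, rules)
        idx.index.setdefault(key, set()).add((cid, term))
        n_tokens = len(token_re.findall(term))
        idx.max_term_tokens = max(idx.max_term_tokens, n_tokens)
    return idx


def dictionary_tag(
    doc: Document,
    index: TermIndex,
    direction: Literal["leftmost", "rightmost"] = "leftmost",
    source: str = "lex",
) -> List[Annotation]:
    """Scan a document for lexicon terms, longest match first.

    Tokens are maximal alphanumeric runs (separators ``-`` ``/`` are token
    boundaries in alias mode, in-token characters in exact mode).  At each
    position the longest window (up to the index's longest term) whose
    normalized surface is an index key is emitted as a non-overlapping
    annotation carrying all matching concept ids; scanning resumes after
    the match.  ``rightmost`` scans from the end of the document instead.
    """
    token_spans = [m.span() for m in index.token_re().finditer(doc.text)]
    n = len(token_spans)
    max_w = max(index.max_term_tokens, 1)
    annotations: List[Annotation] = []

    if direction == "leftmost":
        i = 0
        while i < n:
            hit = _longest_at(doc.text, token_spans, i, max_w, index)
            if hit is None:
                i += 1
                continue
            w, ann = hit
            annotations.append(
                Annotation(
                    doc_id=doc.doc_id,
                    start=ann[0],
                    end=ann[1],
                    surface=doc.text[ann[0] : ann[1]],
                    concept_ids=ann[2],
                    source=source,
                )
            )
            i += w
    else:
        i = n - 1
        while i >= 0:
            # longest window ENDING at token i
            best = None
            for w in range(min(max_w, i + 1), 0, -1):
                start = token_spans[i - w + 1][0]
                end = token_spans[i][1]
                hits = index.lookup(doc.text[start:end])
                if hits:
                    best = (w, start, end, frozenset(c for c, _ in hits))
                    break
            if best is None:
                i -= 1
                continue
            w, start, end, cids = best
            annotations.append(
                Annotation(
                    doc_id=doc.doc_id,
                    start=start,
                    end=end,
                    surface=doc.text[start:end],
                    concept_ids=cids,
                    source=source,
                )
            )
            i -= w
        annotations.reverse()
    return annotations


def _longest_at(text, token_spans, i, max_w, index):
    n = len(token_spans)
    for w in range(min(max_w, n - i), 0, -1):
        start = token_spans[i][0]
        end = token_spans[i + w - 1][1]
        hits = index.lookup(text[start:end])
        if hits:
            return w, (start, end, frozenset(c for c, _ in hits))
    return None


class ConfigurationError(ValueError):
    """A required configuration value (e.g. the reference term) is missing."""


def frequency_filter(
    annotations: Sequence[Annotation],
    freq: FrequencyList,
    ref_term: str = "insulin",
    case_fold: bool = True,
) -> List[Annotation]:
    """Drop annotations whose surface is more frequent than the reference.

    Tagged names that occur in a general-English background corpus at a
    rate strictly higher than a domain-typical reference term ("insulin")
    are too unspecific to be gene or protein mentions and are removed;
    surfaces absent from the background list, or at most as frequent as the
    reference, are kept.  Order is preserved.
    """
    ref_rate = freq.rate(ref_term)
    if ref_rate is None:
        raise ConfigurationError(
            f"reference term {ref_term!r} absent from frequency list"
        )
    kept = []
    for ann in annotations:
        key = ann.surface.casefold() if case_fold else ann.surface
        rate = freq.rate(key)
        if rate is None or rate <= ref_rate:
            kept.append(ann)
    return kept


def prefilter_lexicon(
    lexicon: Lexicon,
    freq: FrequencyList,
    ref_term: str = "insulin",
    case_fold: bool = True,
) -> Lexicon:
    """Equivalent pre-tagging optimisation of :func:`frequency_filter`.

    Removes from the lexicon every term the post-tagging filter would drop,
    so tagging with the filtered lexicon equals tagging-then-filtering
    whenever the removed terms never participate in longer matches.
    """
    ref_rate = freq.rate(ref_term)
    if ref_rate is None:
        raise ConfigurationError(
            f"reference term {ref_term!r} absent from frequency list"
        )
    entries = {}
    for cid, terms in lexicon.entries.items():
        kept = set()
        for t in terms:
            key = t.casefold() if case_fold else t
            rate = freq.rate(key)
            if rate is None or rate <= ref_rate:
                kept.add(t)
        if kept:
            entries[cid] = kept
    return Lexicon(name=f"{lexicon.name}|freq<= {ref_term}", entries=entries)


@dataclass(frozen=True)
class CrossTagResult:
    """Share of one lexicon's terms recovered by tagging with another."""

    tagger_name: str
    corpus_name: str
    n_target: int
    n_matched: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.n_matched / self.n_target, 1)


def cross_tag(tagger_lex: Lexicon, target_lex: Lexicon, mode: Mode) -> CrossTagResult:
    """Tag every unique term of ``target_lex`` with ``tagger_lex``'s index.

    Each target term is treated as a one-term document; it counts as
    matched when some dictionary match covers the whole (trimmed) term.
    """
    if not target_lex.all_terms():
        raise ValueError("empty target lexicon")
    if not tagger_lex.all_terms():
        raise ValueError("empty tagger lexicon")
    index = build_index(tagger_lex, mode)
    targets = sorted(target_lex.all_terms())
    n_matched = 0
    for term in targets:
        text = term.strip()
        doc = Document(doc_id="t", text=text)
        for ann in dictionary_tag(doc, index):
            if ann.start == 0 and ann.end == len(text):
                n_matched += 1
                break
    return CrossTagResult(
        tagger_name=tagger_lex.name,
        corpus_name=target_lex.name,
        n_target=len(targets),
        n_matched=n_matched,
    )
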