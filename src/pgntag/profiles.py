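"""Error profiles: frequency-ranked FP/FN surfaces, their correlation and
clustering, and rule-based error categorization.

A tagger–corpus pair is characterised by the surface strings it gets wrong:
the most frequent false-positive (or false-negative) surfaces, counted with
multiplicity and normalized by the corpus's gold annotation count.  Two
profiles are compared by the Pearson correlation of their count vectors
aligned over the union of surfaces; profiles are clustered agglomeratively
with complete linkage via the Lance–Williams recurrence on the distance
1 − r.  False negatives are dictated by a corpus's annotation standard, so
FN profiles group by corpus; false positives are dictated by the tagger's
resources and filters, so FP profiles group by tagger.

Each frequent error is also assigned one of the morphological/semantic
categories — 1C, 2C (one/two-character artifacts), a-PG (acronym name),
ea-PG (acronym + head noun, semantics preserved), xa-PG (acronym + other
expansion, semantics modified), PGT (long-form name), BMT (other biomedical
term), GE (general English) — rolled up by task relevance into Core
({a-PG, PGT}), Margin ({2C, ea-PG, BMT}) and Artefact ({1C, xa-PG, GE}).
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as importlib_resources
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .evaluate import MatchResult
from .lexmatch import TermIndex, build_index, normalize_term
from .model import Lexicon


def collect_errors(result: MatchResult, kind: Literal["FP", "FN"]) -> Counter:
    """Multiset of error surfaces (case-preserved) from a match result."""
    anns = result.fp if kind == "FP" else result.fn
    return Counter(a.surface for a in anns)


@dataclass
class ErrorProfile:
    """Top-N error surfaces for one (tagger, corpus, kind) triple."""

    tagger: str
    corpus: str
    kind: Literal["FP", "FN"]
    entries: List[Tuple[str, int]]
    cutoff: int = 100
    normalizer: int = 0

    @property
    def label(self) -> str:
        return f"{self.tagger}:{self.corpus}:{self.kind}"

    def counts(self) -> Dict[str, int]:
        return dict(self.entries)

    def rates(self) -> Dict[str, float]:
        return {s: c / self.normalizer for s, c in self.entries}


def build_profile(
    errors: Mapping[str, int],
    cutoff: int = 100,
    normalizer: int = 1,
    tagger: str = "",
    corpus: str = "",
    kind: Literal["FP", "FN"] = "FP",
) -> ErrorProfile:
    """Top-``cutoff`` error surfaces, descending count, lexicographic ties."""
    if normalizer <= 0:
        raise ValueError("normalizer (gold annotation count) must be positive")
    ranked = sorted(errors.items(), key=lambda kv: (-kv[1], kv[0]))
    return ErrorProfile(
        tagger=tagger, corpus=corpus, kind=kind,
        entries=ranked[:cutoff], cutoff=cutoff, normalizer=normalizer,
    )


class NoVarianceError(ValueError):
    """Pearson correlation undefined: an aligned count vector is constant."""


def aligned_vectors(p1: ErrorProfile, p2: ErrorProfile) -> Tuple[np.ndarray, np.ndarray]:
    """Count vectors over the union of both profiles' surfaces (absent = 0)."""
    keys = sorted(set(p1.counts()) | set(p2.counts()))
    c1, c2 = p1.counts(), p2.counts()
    v1 = np.array([c1.get(k, 0) for k in keys], dtype=float)
    v2 = np.array([c2.get(k, 0) for k in keys], dtype=float)
    return v1, v2


def profile_correlation(p1: ErrorProfile, p2: ErrorProfile) -> float:
    """Pearson r of the union-aligned count vectors."""
    v1, v2 = aligned_vectors(p1, p2)
    if len(v1) < 2 or np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise NoVarianceError(
            f"correlation undefined between {p1.label} and {p2.label}: "
            "an aligned vector has no variance"
        )
    r = float(np.corrcoef(v1, v2)[0, 1])
    return max(-1.0, min(1.0, r))


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists (cluster_a, cluster_b, height, size) in merge order,
    scipy linkage-style: leaves are 0..n-1, the i-th merge creates cluster
    n+i.  ``labels`` names the leaves.
    """

    merges: List[Tuple[int, int, float, int]]
    labels: List[str]

    def cut(self, k: int) -> List[Set[int]]:
        """Partition the leaves into ``k`` clusters (undo the last k−1 merges)."""
        n = len(self.labels)
        if not (1 <= k <= n):
            raise ValueError(f"k={k} outside [1, {n}]")
        members: Dict[int, Set[int]] = {i: {i} for i in range(n)}
        for idx, (a, b, _h, _sz) in enumerate(self.merges[: n - k]):
            members[n + idx] = members.pop(a) | members.pop(b)
        return sorted(members.values(), key=lambda s: min(s))


def cluster_profiles(profiles: Sequence[ErrorProfile]) -> Dendrogram:
    """Complete-linkage agglomerative clustering on distance 1 − Pearson r.

    Cluster distances are maintained with the Lance–Williams recurrence
    with complete-linkage coefficients (α₁ = α₂ = ½, β = 0, γ = ½), i.e.
    d(k, i∪j) = max(d(k,i), d(k,j)).  Merge order is deterministic: the
    minimum-distance pair, ties broken by the smaller cluster-index pair.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("clustering needs at least two profiles")
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = profile_correlation(profiles[i], profiles[j])
            except NoVarianceError as exc:
                raise NoVarianceError(
                    f"cannot cluster: pair ({profiles[i].label}, "
                    f"{profiles[j].label}) has undefined correlation"
                ) from exc
            dist[(i, j)] = 1.0 - r

    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges: List[Tuple[int, int, float, int]] = []
    next_id = n

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (d(a, b), a, b)
                if best is None or key < best:
                    best = key
        height, a, b = best
        new_size = sizes[a] + sizes[b]
        # Lance-Williams update, complete linkage: 1/2 d_ka + 1/2 d_kb + 1/2 |d_ka - d_kb|
        for k in active:
            if k in (a, b):
                continue
            dka, dkb = d(k, a), d(k, b)
            dnew = 0.5 * dka + 0.5 * dkb + 0.5 * abs(dka - dkb)
            dist[(k, next_id) if k < next_id else (next_id, k)] = dnew
        active = [k for k in active if k not in (a, b)] + [next_id]
        sizes[next_id] = new_size
        merges.append((a, b, height, new_size))
        next_id += 1
    return Dendrogram(merges=merges, labels=[p.label for p in profiles])


class ErrorCategory(str, Enum):
    C1 = "1C"
    C2 = "2C"
    A_PG = "a-PG"
    EA_PG = "ea-PG"
    XA_PG = "xa-PG"
    PGT = "PGT"
    BMT = "BMT"
    GE = "GE"
    UNK = "UNK"


class Relevance(str, Enum):
    CORE = "Core"
    MARGIN = "Margin"
    ARTEFACT = "Artefact"


RELEVANCE_OF: Dict[ErrorCategory, Relevance] = {
    ErrorCategory.A_PG: Relevance.CORE,
    ErrorCategory.PGT: Relevance.CORE,
    ErrorCategory.C2: Relevance.MARGIN,
    ErrorCategory.EA_PG: Relevance.MARGIN,
    ErrorCategory.BMT: Relevance.MARGIN,
    ErrorCategory.C1: Relevance.ARTEFACT,
    ErrorCategory.XA_PG: Relevance.ARTEFACT,
    ErrorCategory.GE: Relevance.ARTEFACT,
    # UNK is an artifact-only fallback, excluded from relevance rollups
}

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass
class CategoryResources:
    """Term lists the categorization cascade consults."""

    lexicon: Lexicon
    head_nouns: Set[str] = field(default_factory=lambda: {
        "gene", "genes", "protein", "proteins", "family", "receptor",
    })
    general_english: Set[str] = field(default_factory=set)
    biomedical_terms: Set[str] = field(default_factory=set)
    short_form_max_len: int = 6

    def __post_init__(self) -> None:
        self._index = build_index(self.lexicon, "alias") if self.lexicon.entries else None
        self._ge = {t.casefold() for t in self.general_english}
        self._bmt = {t.casefold() for t in self.biomedical_terms}
        self._heads = {t.casefold() for t in self.head_nouns}

    def in_lexicon(self, surface: str) -> bool:
        if self._index is None:
            return False
        return bool(self._index.lookup(surface))


def default_resources() -> CategoryResources:
    """Packaged term lists covering the documented category examples."""
    def _load(name: str) -> List[str]:
        text = (
            importlib_resources.files("pgntag.resources").joinpath(name).read_text("utf-8")
        )
        return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]

    lex_entries: Dict[str, Set[str]] = defaultdict(set)
    for i, term in enumerate(_load("pgn_terms.txt")):
        lex_entries[f"PGN{i:04d}"].add(term)
    return CategoryResources(
        lexicon=Lexicon(name="category-pgn", entries=dict(lex_entries)),
        general_english=set(_load("general_english.txt")),
        biomedical_terms=set(_load("biomedical_terms.txt")),
    )


def _is_short_form(surface: str, max_len: int) -> bool:
    if len(surface) <= max_len:
        return True
    if any(ch.isdigit() for ch in surface):
        return True
    core = surface[1:]
    return any(ch.isupper() for ch in core)


def categorize_error(surface: str, res: CategoryResources) -> ErrorCategory:
    """Deterministic rule cascade; first matching rule wins.

    1. one alphanumeric character -> 1C;  2. two -> 2C;
    3. single general-English token not in the lexicon -> GE;
    4. whole surface matches the lexicon (alias mode): short form
       (<= 6 chars, or contains digits or internal capitals) -> a-PG,
       otherwise -> PGT;
    5. lexicon-matching prefix + trailing head noun(s) -> ea-PG;
    6. lexicon-matching prefix + other trailing token(s) -> xa-PG;
    7. surface in the biomedical-term list -> BMT;
    8. multi-token or biomedical-looking single token -> BMT; else UNK.
    """
    if not surface or not surface.strip():
        raise ValueError("empty surface")
    alnum = [ch for ch in surface if ch.isalnum()]
    if len(alnum) == 1:
        return ErrorCategory.C1
    if len(alnum) == 2:
        return ErrorCategory.C2
    words = _WORD_RE.findall(surface)
    if len(words) == 1 and surface.casefold() in res._ge and not res.in_lexicon(surface):
        return ErrorCategory.GE
    if res.in_lexicon(surface):
        if _is_short_form(surface.strip(), res.short_form_max_len):
            return ErrorCategory.A_PG
        return ErrorCategory.PGT
    # longest lexicon-matching token prefix with a remainder
    if len(words) > 1 and res._index is not None:
        spans = [m.span() for m in _WORD_RE.finditer(surface)]
        for k in range(len(words) - 1, 0, -1):
            prefix = surface[: spans[k - 1][1]]
            if res.in_lexicon(prefix):
                tail = [w.casefold() for w in words[k:]]
                if all(w in res._heads for w in tail):
                    return ErrorCategory.EA_PG
                return ErrorCategory.XA_PG
    if surface.casefold() in res._bmt:
        return ErrorCategory.BMT
    if len(words) > 1:
        return ErrorCategory.BMT
    token = words[0] if words else surface
    biomedical_looking = (
        any(ch.isdigit() for ch in token)
        or any(ch.isupper() for ch in token[1:])
        or bool(_GREEK_RE.search(token))
        or "-" in surface
        or "/" in surface
    )
    return ErrorCategory.BMT if biomedical_looking else ErrorCategory.UNK


_GREEK_RE = re.compile(r"[Ͱ-Ͽἀ-῿]")


@dataclass
class CategoryTable:
    """Per-category error counts and rates with the relevance rollup."""

    kind: Literal["FP", "FN"]
    counts: Dict[ErrorCategory, int]
    rates: Dict[ErrorCategory, float]
    rollup_counts: Dict[Relevance, int]
    rollup_rates: Dict[Relevance, float]
    unk_count: int
    normalizer: int


def aggregate_top_errors(
    result: MatchResult,
    resources: CategoryResources,
    kind: Literal["FP", "FN"] = "FP",
    k: int = 15,
    normalizer: int = 1,
) -> CategoryTable:
    """Categorize the top-``k`` most frequent errors and roll up by relevance.

    Counts are summed per category over the top-k surfaces (with their
    multiplicities) and normalized by the corpus's total gold annotations.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    errors = collect_errors(result, kind)
    top = sorted(errors.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    counts: Dict[ErrorCategory, int] = {c: 0 for c in ErrorCategory}
    for surface, cnt in top:
        counts[categorize_error(surface, resources)] += cnt
    rollup: Dict[Relevance, int] = {rel: 0 for rel in Relevance}
    for cat, rel in RELEVANCE_OF.items():
        rollup[rel] += counts[cat]
    return CategoryTable(
        kind=kind,
        counts={c: counts[c] for c in ErrorCategory if c != ErrorCategory.UNK},
        rates={c: counts[c] / normalizer for c in ErrorCategory if c != ErrorCategory.UNK},
        rollup_counts=rollup,
        rollup_rates={rel: v / normalizer for rel, v in rollup.items()},
        unk_count=counts[ErrorCategory.UNK],
        normalizer=normalizer,
    )
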