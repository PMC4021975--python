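"""Core data model for gene/protein-name tagging and evaluation.

The unit of everything downstream is the :class:`Annotation`: a character
span in a document together with the surface string it covers.  Gold
annotations, tagger predictions and error lists are all annotation
collections; corpora bundle documents with their gold (and optionally
alternative) annotations; lexica map concept identifiers to term sets;
frequency lists summarise a background corpus.

Offsets are canonically 0-based, half-open, with whitespace counted.  The
space-free inclusive convention used by some standoff gene-list files (both
ends inclusive, whitespace characters not counted) is supported as a
read/write dialect via :func:`convert_offsets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple


class OffsetDialect(str, Enum):
    """Offset conventions for standoff annotations."""

    #: 0-based, half-open, whitespace counted (the in-memory convention).
    CANONICAL = "canonical"
    #: whitespace not counted, both ends inclusive (BC2 gene-list style).
    SPACE_FREE = "space-free"


@dataclass(frozen=True)
class Document:
    """A piece of text with an opaque identifier."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class Annotation:
    """A character span in a document with its surface string.

    ``concept_ids`` carries the (possibly empty) set of lexicon concepts a
    dictionary tagger resolved the span to; ``source`` labels the producing
    tagger or gold set.  ``dialect`` records the offset convention the
    start/end values are expressed in.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    concept_ids: FrozenSet[str] = frozenset()
    source: str = ""
    dialect: OffsetDialect = OffsetDialect.CANONICAL

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "Annotation") -> bool:
        return (
            self.doc_id == other.doc_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnnotatedCorpus:
    """Documents plus gold annotations and optional alternative annotations.

    Alternatives share their record identifier (``doc_id``) with the main
    gold entry they belong to, BioCreative-II alternative-gene-list style.
    """

    name: str
    documents: List[Document]
    gold: List[Annotation]
    alternatives: List[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError(f"corpus {self.name!r}: duplicate doc_ids")
        known = set(ids)
        for ann in self.gold:
            if ann.doc_id not in known:
                raise ValueError(
                    f"corpus {self.name!r}: annotation doc_id {ann.doc_id!r} "
                    "does not resolve to a document"
                )

    def document(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    @property
    def texts(self) -> Dict[str, str]:
        return {d.doc_id: d.text for d in self.documents}


@dataclass
class Lexicon:
    """Mapping concept-id -> set of terms naming that concept."""

    name: str
    entries: Dict[str, Set[str]]

    @property
    def size(self) -> int:
        """Number of unique terms across all concepts."""
        return len(self.all_terms())

    def all_terms(self) -> Set[str]:
        terms: Set[str] = set()
        for ts in self.entries.values():
            terms |= ts
        return terms

    def items(self) -> Iterable[Tuple[str, str]]:
        for cid, ts in sorted(self.entries.items()):
            for t in sorted(ts):
                yield cid, t


@dataclass
class FrequencyList:
    """Term occurrence counts over a background corpus.

    ``doc_freqs``/``n_docs`` optionally carry document frequencies for IDF
    weighting; ``counts``/``total`` carry raw occurrence counts for
    frequency-rate filtering.
    """

    counts: Dict[str, int]
    doc_freqs: Optional[Dict[str, int]] = None
    n_docs: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count in frequency list")
        if self.doc_freqs is not None:
            for t, df in self.doc_freqs.items():
                if not (0 <= df <= self.n_docs):
                    raise ValueError(
                        f"doc_freq[{t!r}]={df} outside [0, n_docs={self.n_docs}]"
                    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rate(self, term: str) -> Optional[float]:
        """Occurrence rate of ``term`` (case-folded lookup), None if absent."""
        c = self.counts.get(term)
        if c is None:
            c = self.counts.get(term.casefold())
        if c is None:
            return None
        total = self.total
        return c / total if total else 0.0


def _nonspace_index_maps(text: str) -> Tuple[List[int], Dict[int, int]]:
    """Canonical positions of non-whitespace chars, and the inverse map."""
    positions = [i for i, ch in enumerate(text) if not ch.isspace()]
    inverse = {canon: sf for sf, canon in enumerate(positions)}
    return positions, inverse


def convert_offsets(
    ann: Annotation,
    text: str,
    from_dialect: OffsetDialect,
    to_dialect: OffsetDialect,
) -> Annotation:
    """Convert an annotation between offset conventions.

    Whitespace at the span boundaries is not representable in the
    space-free convention, so spans are expected to start and end on
    non-whitespace characters (gene-list spans always do).
    """
    if from_dialect == to_dialect:
        return replace(ann, dialect=to_dialect)
    positions, inverse = _nonspace_index_maps(text)
    if from_dialect == OffsetDialect.CANONICAL:
        start, end = ann.start, ann.end
        if not (0 <= start < end <= len(text)):
            raise ValueError(f"span ({start},{end}) out of range for text")
        # snap inward off boundary whitespace so the span maps losslessly
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if start == end:
            raise ValueError("whitespace-only span cannot be converted")
        sf_start = inverse[start]
        sf_end = inverse[end - 1]
        return replace(ann, start=sf_start, end=sf_end,
                       dialect=OffsetDialect.SPACE_FREE)
    # space-free inclusive -> canonical
    sf_start, sf_end = ann.start, ann.end
    if not (0 <= sf_start <= sf_end < len(positions)):
        raise ValueError(
            f"space-free span ({sf_start},{sf_end}) out of range "
            f"({len(positions)} non-whitespace characters)"
        )
    start = positions[sf_start]
    end = positions[sf_end] + 1
    return replace(ann, start=start, end=end, dialect=OffsetDialect.CANONICAL)


def check_surface(ann: Annotation, text: str) -> bool:
    """True iff the annotation's surface equals text[start:end] (canonical)."""
    if ann.dialect != OffsetDialect.CANONICAL:
        raise ValueError("surface check requires canonical offsets")
    return text[ann.start : ann.end] == ann.surface
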