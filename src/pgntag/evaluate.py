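"""Span matching and precision/recall/F1 scoring.

Two matching regimes are supported.  *Exact* matching pairs a prediction
with a gold mention only on identical character spans.  *cos98* soft
matching pairs spans whose surface strings are near-identical under an
IDF-weighted cosine similarity: every token is weighted by its inverse
document frequency over a background corpus, so two annotated strings that
differ only by low-information tokens ("the", "protein") still exceed the
0.98 similarity cut, while differences in informative tokens do not.

Gold sets may carry *alternative* annotations — additional acceptable
spans per gene record, BioCreative-II alternative-gene-list style.  The
``tier1`` policy re-credits false positives that hit an alternative of an
already-matched gene; ``tier1+tier2`` additionally credits alternatives of
otherwise-missed genes and cancels the corresponding false negatives.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

from .model import AnnotatedCorpus, Annotation, FrequencyList

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass
class IdfTable:
    """Inverse document frequencies: idf(t) = ln(D / d_t).

    Tokens never seen in the background are given d_t = 0.5 (half an
    occurrence), i.e. idf = ln(2D); tokens present in every document get
    weight 0, which is exactly what makes ubiquitous tokens ignorable in
    soft matching.
    """

    n_docs: int
    doc_freqs: Dict[str, int]

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("IDF table needs at least one background document")

    def idf(self, token: str) -> float:
        d_t = self.doc_freqs.get(token, 0.5)
        if d_t <= 0:
            d_t = 0.5
        return math.log(self.n_docs / d_t)


def build_idf(background) -> IdfTable:
    """Build an IDF table from documents or a frequency list with doc_freqs."""
    if isinstance(background, FrequencyList):
        if not background.doc_freqs or background.n_docs < 1:
            raise ValueError("frequency list lacks document frequencies")
        return IdfTable(n_docs=background.n_docs, doc_freqs=dict(background.doc_freqs))
    docs = list(background)
    if not docs:
        raise ValueError("empty background corpus")
    doc_freqs: Dict[str, int] = defaultdict(int)
    for doc in docs:
        text = doc.text if hasattr(doc, "text") else str(doc)
        for tok in set(_tokens(text)):
            doc_freqs[tok] += 1
    return IdfTable(n_docs=len(docs), doc_freqs=dict(doc_freqs))


def _tokens(s: str) -> List[str]:
    return [t.casefold() for t in _TOKEN_RE.findall(s)]


def weight_vector(s: str, idf: IdfTable) -> Dict[str, float]:
    """IDF-weighted token vector of a string (case-folded alnum tokens)."""
    vec: Dict[str, float] = defaultdict(float)
    for tok in _tokens(s):
        vec[tok] += idf.idf(tok)
    return dict(vec)


def cosine_similarity(a: str, b: str, idf: IdfTable) -> float:
    """IDF-weighted cosine similarity of two annotated strings in [0, 1].

    If both vectors have zero norm the strings carry no weighable content:
    returns 1.0 when their token sets are equal, else 0.0; a single
    zero-norm side gives 0.0.
    """
    va, vb = weight_vector(a, idf), weight_vector(b, idf)
    na = math.sqrt(sum(w * w for w in va.values()))
    nb = math.sqrt(sum(w * w for w in vb.values()))
    if na == 0.0 and nb == 0.0:
        return 1.0 if set(_tokens(a)) == set(_tokens(b)) else 0.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    dot = sum(w * vb.get(t, 0.0) for t, w in va.items())
    return dot / (na * nb)


@dataclass
class EvalConfig:
    mode: Literal["exact", "cos98"] = "exact"
    threshold: float = 0.98
    require_overlap: bool = True
    alternatives_policy: Literal["ignore", "tier1", "tier1+tier2"] = "ignore"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class MatchResult:
    """One-to-one pairing of gold and predicted annotations."""

    tp_pairs: List[Tuple[Annotation, Annotation]]
    fp: List[Annotation]
    fn: List[Annotation]
    config: EvalConfig

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def compute_metrics(tp: int, fp: int, fn: int) -> Metrics:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R); 0 on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("negative count")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return Metrics(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def match(
    gold: Sequence[Annotation],
    pred: Sequence[Annotation],
    config: EvalConfig,
    idf: Optional[IdfTable] = None,
) -> MatchResult:
    """One-to-one match of predictions to gold, per document.

    exact mode: identical spans.  cos98 mode: candidate pairs must overlap
    positionally (when ``require_overlap``) and exceed the similarity
    threshold strictly; candidates commit greedily in order of descending
    similarity, ties broken by (gold start, prediction start).
    """
    if config.mode == "cos98" and idf is None:
        raise ValueError("cos98 matching requires an IDF table")
    gold_by_doc: Dict[str, List[Tuple[int, Annotation]]] = defaultdict(list)
    pred_by_doc: Dict[str, List[Tuple[int, Annotation]]] = defaultdict(list)
    for i, g in enumerate(gold):
        gold_by_doc[g.doc_id].append((i, g))
    for j, p in enumerate(pred):
        pred_by_doc[p.doc_id].append((j, p))

    matched_gold: Dict[int, int] = {}
    matched_pred: Dict[int, int] = {}
    for doc_id, gs in gold_by_doc.items():
        ps = pred_by_doc.get(doc_id, [])
        if not ps:
            continue
        if config.mode == "exact":
            span_index: Dict[Tuple[int, int], List[int]] = defaultdict(list)
            for j, p in ps:
                span_index[p.span].append(j)
            for i, g in gs:
                for j in span_index.get(g.span, ()):
                    if j not in matched_pred:
                        matched_gold[i] = j
                        matched_pred[j] = i
                        break
        else:
            candidates = []
            for i, g in gs:
                for j, p in ps:
                    if config.require_overlap and not g.overlaps(p):
                        continue
                    sim = cosine_similarity(g.surface, p.surface, idf)
                    if sim > config.threshold:
                        # identical spans outrank other equal-similarity pairs,
                        # so soft matching never undercuts exact matching
                        candidates.append(
                            (-sim, 0 if g.span == p.span else 1,
                             g.start, p.start, i, j)
                        )
            candidates.sort()
            for _negsim, _exact, _gs, _ps, i, j in candidates:
                if i not in matched_gold and j not in matched_pred:
                    matched_gold[i] = j
                    matched_pred[j] = i

    tp_pairs = [(gold[i], pred[j]) for i, j in sorted(matched_gold.items())]
    fp = [p for j, p in enumerate(pred) if j not in matched_pred]
    fn = [g for i, g in enumerate(gold) if i not in matched_gold]
    return MatchResult(tp_pairs=tp_pairs, fp=fp, fn=fn, config=config)


def _record_key(ann: Annotation) -> str:
    return ann.doc_id


def _matches_one(pred: Annotation, alt: Annotation, config: EvalConfig,
                 idf: Optional[IdfTable]) -> bool:
    if pred.doc_id != alt.doc_id:
        return False
    if config.mode == "exact":
        return pred.span == alt.span
    if config.require_overlap and not pred.overlaps(alt):
        return False
    return cosine_similarity(alt.surface, pred.surface, idf) > config.threshold


def evaluate_with_alternatives(
    gold: Sequence[Annotation],
    alternatives: Sequence[Annotation],
    pred: Sequence[Annotation],
    config: EvalConfig,
    idf: Optional[IdfTable] = None,
) -> Metrics:
    """Score predictions against gold with alternative-span credit.

    ``ignore``: alternatives unused.  ``tier1``: a false positive is
    re-scored as a true positive when it matches an alternative of a gene
    whose main annotation was itself matched.  ``tier1+tier2``: a false
    positive matching an alternative of an *unmatched* gene also scores,
    and cancels that gene's false negative.  Each gene record yields at
    most one alternative-based credit.
    """
    gold_ids = {_record_key(g) for g in gold}
    for alt in alternatives:
        if _record_key(alt) not in gold_ids:
            raise ValueError(
                f"alternative references unknown gene record {_record_key(alt)!r}"
            )
    base = match(gold, pred, config, idf)
    tp, fp_list, fn_list = base.tp, list(base.fp), list(base.fn)
    policy = config.alternatives_policy
    if policy == "ignore" or not alternatives:
        return compute_metrics(tp, len(fp_list), len(fn_list))

    alts_by_record: Dict[str, List[Annotation]] = defaultdict(list)
    for alt in alternatives:
        alts_by_record[_record_key(alt)].append(alt)
    matched_records = {_record_key(g) for g, _p in base.tp_pairs}
    unmatched_records = {_record_key(g) for g in base.fn}
    credited: set = set()

    def _rescue_pass(fps: List[Annotation], eligible: set) -> List[Annotation]:
        nonlocal tp, fn_list
        remaining = []
        for p in fps:
            rescued = False
            for record in sorted(alts_by_record):
                if record in credited or record not in eligible:
                    continue
                if any(_matches_one(p, alt, config, idf)
                       for alt in alts_by_record[record]):
                    credited.add(record)
                    tp += 1
                    if record in unmatched_records:
                        fn_list = [g for g in fn_list if _record_key(g) != record]
                        unmatched_records.discard(record)
                    rescued = True
                    break
            if not rescued:
                remaining.append(p)
        return remaining

    # tier1 rescues first; tier2 rescues only compete for what tier1 left,
    # which makes tier1+tier2 credit a superset of tier1's.
    fp_list = _rescue_pass(fp_list, matched_records)
    if policy == "tier1+tier2":
        fp_list = _rescue_pass(fp_list, set(unmatched_records))
    return compute_metrics(tp, len(fp_list), len(fn_list))


def evaluate_corpus(
    corpus: AnnotatedCorpus,
    pred: Sequence[Annotation],
    config: EvalConfig,
    idf: Optional[IdfTable] = None,
) -> Metrics:
    """Convenience: score predictions against a corpus's gold/alternatives."""
    if config.alternatives_policy != "ignore" and corpus.alternatives:
        return evaluate_with_alternatives(
            corpus.gold, corpus.alternatives, pred, config, idf
        )
    res = match(corpus.gold, pred, config, idf)
    return compute_metrics(res.tp, len(res.fp), len(res.fn))
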