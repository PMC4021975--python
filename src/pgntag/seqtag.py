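"""Linear-chain sequence tagging of gene/protein mentions.

The feature template is the classic character-shape battery for gene
mentions: all character n-grams of length 2–4, capitalization flags
(starts/ends with a capital, all capitals), token-length buckets (1, 2,
3–5 characters), digit-content flags (exactly one digit, exactly two
digits, all digits), and the presence of punctuation or a Greek character
— each token's features additionally conjoined with its neighbours' at
offsets −2…+2 ("offset conjunctions").

The model is a first-order linear chain over BIO labels trained with the
averaged structured perceptron and decoded with Viterbi.  Training and
prediction are deterministic given (corpus, config, seed).

The module also provides :func:`fp_filter`: keeping a dictionary tagger's
annotation only when the sequence model confirms it (span overlap or exact
span equality), the precision-oriented hybrid used to clean lexical
tagging output.
"""

from __future__ import annotations

import logging
import random
import re
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence, Tuple

from .model import AnnotatedCorpus, Annotation, Document

logger = logging.getLogger(__name__)

LABELS = ("O", "B", "I")

_TOKEN_RE = re.compile(r"[^\W_]+|[^\w\s]", re.UNICODE)
_GREEK_RE = re.compile(r"[Ͱ-Ͽἀ-῿]")


@dataclass(frozen=True)
class TokenSequence:
    doc_id: str
    tokens: Tuple[str, ...]
    spans: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(doc: Document) -> TokenSequence:
    """Split into maximal alphanumeric runs plus single punctuation chars."""
    tokens, spans = [], []
    for m in _TOKEN_RE.finditer(doc.text):
        tokens.append(m.group())
        spans.append(m.span())
    return TokenSequence(doc_id=doc.doc_id, tokens=tuple(tokens), spans=tuple(spans))


def _token_features(token: str) -> List[str]:
    feats = []
    for n in (2, 3, 4):
        for i in range(len(token) - n + 1):
            feats.append(f"ng{n}={token[i:i + n]}")
    if token[:1].isupper():
        feats.append("cap:start")
    if token[-1:].isupper():
        feats.append("cap:end")
    if len(token) > 1 and token.isupper():
        feats.append("cap:all")
    L = len(token)
    if L == 1:
        feats.append("len=1")
    elif L == 2:
        feats.append("len=2")
    elif 3 <= L <= 5:
        feats.append("len=3-5")
    n_digits = sum(ch.isdigit() for ch in token)
    if token.isdigit():
        feats.append("dig:all")
    elif n_digits == 1:
        feats.append("dig=1")
    elif n_digits == 2:
        feats.append("dig=2")
    if any(not ch.isalnum() and not ch.isspace() for ch in token):
        feats.append("punct")
    if _GREEK_RE.search(token):
        feats.append("greek")
    feats.append(f"w={token.lower()}")
    return feats


def extract_features(tokens: TokenSequence, i: int) -> List[str]:
    """Feature strings for position ``i``, window ±2 offset-conjoined."""
    if not (0 <= i < len(tokens)):
        raise IndexError(f"position {i} out of range for {len(tokens)} tokens")
    feats: List[str] = []
    for off in (-2, -1, 0, 1, 2):
        j = i + off
        if 0 <= j < len(tokens):
            feats.extend(f"[{off}]{f}" for f in _token_features(tokens.tokens[j]))
        else:
            feats.append(f"[{off}]<edge>")
    return feats


def encode_bio(doc: Document, gold: Sequence[Annotation]) -> Tuple[TokenSequence, List[str]]:
    """Token-level BIO labels for a document's gold mentions.

    Mention boundaries that split a token snap outward to the covering
    token; overlapping gold mentions resolve in favour of the longer one.
    """
    toks = tokenize(doc)
    labels = ["O"] * len(toks)
    anns = sorted(
        (a for a in gold if a.doc_id == doc.doc_id),
        key=lambda a: (a.end - a.start),
        reverse=True,
    )
    claimed = [False] * len(toks)
    selected = []
    for ann in anns:
        idxs = [
            k for k, (s, e) in enumerate(toks.spans) if s < ann.end and ann.start < e
        ]
        if not idxs:
            continue
        if any(claimed[k] for k in idxs):
            logger.warning(
                "overlapping gold mentions in %s at %d-%d; longer one wins",
                doc.doc_id, ann.start, ann.end,
            )
            continue
        if toks.spans[idxs[0]][0] != ann.start or toks.spans[idxs[-1]][1] != ann.end:
            logger.warning(
                "gold span (%d,%d) in %s snapped to token boundaries (%d,%d)",
                ann.start, ann.end, doc.doc_id,
                toks.spans[idxs[0]][0], toks.spans[idxs[-1]][1],
            )
        for k in idxs:
            claimed[k] = True
        selected.append(idxs)
    for idxs in selected:
        labels[idxs[0]] = "B"
        for k in idxs[1:]:
            labels[k] = "I"
    return toks, labels


def decode_bio(labels: Sequence[str], tokens: TokenSequence, text: str,
               source: str = "ml") -> List[Annotation]:
    """Turn a BIO label sequence back into mention annotations."""
    anns: List[Annotation] = []
    start_idx = None
    for k, lab in enumerate(list(labels) + ["O"]):
        in_mention = start_idx is not None
        if lab == "B" or (lab == "I" and not in_mention):
            if in_mention:
                anns.append(_span_ann(tokens, start_idx, k - 1, text, source))
            start_idx = k
        elif lab == "O" and in_mention:
            anns.append(_span_ann(tokens, start_idx, k - 1, text, source))
            start_idx = None
    return anns


def _span_ann(tokens: TokenSequence, i: int, j: int, text: str, source: str) -> Annotation:
    start = tokens.spans[i][0]
    end = tokens.spans[j][1]
    return Annotation(
        doc_id=tokens.doc_id, start=start, end=end,
        surface=text[start:end], source=source,
    )


@dataclass
class TrainConfig:
    seed: int = 0
    epochs: int = 8
    shuffle: bool = True


@dataclass
class SequenceModel:
    """Trained linear-chain model: emission and transition weights."""

    emission: Dict[Tuple[str, str], float]
    transition: Dict[Tuple[str, str], float]
    initial: Dict[str, float]
    config: TrainConfig

    def viterbi(self, feature_seq: Sequence[Sequence[str]]) -> List[str]:
        n = len(feature_seq)
        if n == 0:
            return []
        em = self.emission
        scores = []
        for feats in feature_seq:
            scores.append(
                {lab: sum(em.get((f, lab), 0.0) for f in feats) for lab in LABELS}
            )
        delta = [{lab: self.initial.get(lab, 0.0) + scores[0][lab] for lab in LABELS}]
        back: List[Dict[str, str]] = []
        for t in range(1, n):
            row, brow = {}, {}
            for lab in LABELS:
                best_prev, best_val = None, None
                for prev in LABELS:
                    v = delta[t - 1][prev] + self.transition.get((prev, lab), 0.0)
                    if best_val is None or v > best_val:
                        best_prev, best_val = prev, v
                row[lab] = best_val + scores[t][lab]
                brow[lab] = best_prev
            delta.append(row)
            back.append(brow)
        last = max(LABELS, key=lambda lab: (delta[-1][lab], -LABELS.index(lab)))
        path = [last]
        for brow in reversed(back):
            path.append(brow[path[-1]])
        path.reverse()
        return path


def train(corpus: AnnotatedCorpus, config: TrainConfig | None = None) -> SequenceModel:
    """Fit the linear-chain model on a corpus's gold mentions.

    Averaged structured perceptron: for each document, Viterbi-decode with
    the current weights and update on every feature/transition where the
    prediction disagrees with gold; final weights are the average over all
    updates, which damps oscillation and makes small training sets usable.
    """
    config = config or TrainConfig()
    if not corpus.documents or not corpus.gold:
        raise ValueError("training requires a corpus with at least one annotated document")

    prepared = []
    for doc in corpus.documents:
        toks, labels = encode_bio(doc, corpus.gold)
        if len(toks) == 0:
            continue
        feats = [extract_features(toks, i) for i in range(len(toks))]
        prepared.append((feats, labels))
    if not prepared:
        raise ValueError("no tokenizable documents in training corpus")

    emission: Dict[Tuple[str, str], float] = defaultdict(float)
    transition: Dict[Tuple[str, str], float] = defaultdict(float)
    initial: Dict[str, float] = defaultdict(float)
    em_tot: Dict[Tuple[str, str], float] = defaultdict(float)
    tr_tot: Dict[Tuple[str, str], float] = defaultdict(float)
    in_tot: Dict[str, float] = defaultdict(float)

    model = SequenceModel(emission=emission, transition=transition,
                          initial=initial, config=config)
    rng = random.Random(config.seed)
    order = list(range(len(prepared)))
    steps = 0
    for _epoch in range(config.epochs):
        if config.shuffle:
            rng.shuffle(order)
        for idx in order:
            feats, gold_labels = prepared[idx]
            steps += 1
            pred = model.viterbi(feats)
            if pred == gold_labels:
                continue
            for t, (g, p) in enumerate(zip(gold_labels, pred)):
                if g != p:
                    for f in feats[t]:
                        emission[(f, g)] += 1.0
                        emission[(f, p)] -= 1.0
                        em_tot[(f, g)] += steps
                        em_tot[(f, p)] -= steps
            prev_g = prev_p = None
            for t in range(len(gold_labels)):
                g, p = gold_labels[t], pred[t]
                if t == 0:
                    if g != p:
                        initial[g] += 1.0
                        initial[p] -= 1.0
                        in_tot[g] += steps
                        in_tot[p] -= steps
                else:
                    if (prev_g, g) != (prev_p, p):
                        transition[(prev_g, g)] += 1.0
                        transition[(prev_p, p)] -= 1.0
                        tr_tot[(prev_g, g)] += steps
                        tr_tot[(prev_p, p)] -= steps
                prev_g, prev_p = g, p

    # averaged weights: w_avg = w - accumulated/steps
    if steps:
        avg_em = {k: v - em_tot[k] / steps for k, v in emission.items()}
        avg_tr = {k: v - tr_tot[k] / steps for k, v in transition.items()}
        avg_in = {k: v - in_tot[k] / steps for k, v in initial.items()}
    else:
        avg_em, avg_tr, avg_in = dict(emission), dict(transition), dict(initial)
    return SequenceModel(emission=avg_em, transition=avg_tr, initial=avg_in,
                         config=config)


def predict(model: SequenceModel, doc: Document, source: str = "ml") -> List[Annotation]:
    """Decode mention annotations for a document. Deterministic per model."""
    toks = tokenize(doc)
    if len(toks) == 0:
        return []
    feats = [extract_features(toks, i) for i in range(len(toks))]
    labels = model.viterbi(feats)
    return decode_bio(labels, toks, doc.text, source=source)


def fp_filter(
    lex_annotations: Sequence[Annotation],
    ml_annotations: Sequence[Annotation],
    policy: Literal["overlap", "exact"] = "overlap",
) -> List[Annotation]:
    """Keep a lexical annotation only if a sequence-model annotation confirms it.

    ``overlap``: character spans intersect in the same document (default —
    lexical and learned boundaries rarely agree exactly).  ``exact``:
    identical spans.  Output is a sub-list of the input, order preserved.
    """
    by_doc: Dict[str, List[Annotation]] = defaultdict(list)
    for a in ml_annotations:
        by_doc[a.doc_id].append(a)
    kept = []
    for lex in lex_annotations:
        candidates = by_doc.get(lex.doc_id, ())
        if policy == "exact":
            ok = any(m.span == lex.span for m in candidates)
        else:
            ok = any(lex.overlaps(m) for m in candidates)
        if ok:
            kept.append(lex)
    return kept
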