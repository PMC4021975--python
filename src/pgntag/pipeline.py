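"""Run the full tagger × corpus study matrix.

Every configured tagger is applied to every corpus and scored under every
evaluation mode, producing a league-table of metric rows plus the raw
match results for downstream error profiling.  Pairs are independent: a
failure in one (tagger, corpus) cell is recorded as failed and the rest
continue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import pandas as pd

from .evaluate import EvalConfig, IdfTable, MatchResult, compute_metrics, match
from .lexmatch import build_index, dictionary_tag, frequency_filter
from .model import AnnotatedCorpus, Annotation, FrequencyList, Lexicon
from .seqtag import SequenceModel, TrainConfig, fp_filter, predict, train

logger = logging.getLogger(__name__)

LEAGUE_COLUMNS = [
    "corpus", "tagger", "mode", "tp", "fp", "fn", "precision", "recall", "f1",
]


@dataclass
class TaggerSpec:
    """One tagging solution: dictionary, sequence model, or hybrid.

    ``lex``: dictionary tagging with ``lexicon`` in ``mode``, optionally
    frequency-filtered against ``freq``.  ``ml``: sequence model trained on
    ``train_corpus``.  ``hybrid``: dictionary tagging whose output is
    FP-filtered by the sequence model's predictions.
    """

    name: str
    kind: Literal["lex", "ml", "hybrid"] = "lex"
    lexicon: Optional[Lexicon] = None
    match_mode: Literal["exact", "alias"] = "alias"
    freq: Optional[FrequencyList] = None
    ref_term: str = "insulin"
    train_corpus: Optional[AnnotatedCorpus] = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    fp_policy: Literal["overlap", "exact"] = "overlap"

    def build(self) -> "_PreparedTagger":
        index = model = None
        if self.kind in ("lex", "hybrid"):
            if self.lexicon is None:
                raise ValueError(f"tagger {self.name!r}: lexicon required")
            index = build_index(self.lexicon, self.match_mode)
        if self.kind in ("ml", "hybrid"):
            if self.train_corpus is None:
                raise ValueError(f"tagger {self.name!r}: training corpus required")
            model = train(self.train_corpus, self.train_config)
        return _PreparedTagger(spec=self, index=index, model=model)


@dataclass
class _PreparedTagger:
    spec: TaggerSpec
    index: object
    model: Optional[SequenceModel]

    def tag(self, corpus: AnnotatedCorpus) -> List[Annotation]:
        spec = self.spec
        if spec.kind == "ml":
            out: List[Annotation] = []
            for doc in corpus.documents:
                out.extend(predict(self.model, doc, source=spec.name))
            return out
        anns: List[Annotation] = []
        for doc in corpus.documents:
            anns.extend(dictionary_tag(doc, self.index, source=spec.name))
        if spec.freq is not None:
            anns = frequency_filter(anns, spec.freq, ref_term=spec.ref_term)
        if spec.kind == "hybrid":
            ml = []
            for doc in corpus.documents:
                ml.extend(predict(self.model, doc, source=spec.name + "/seq"))
            anns = fp_filter(anns, ml, policy=spec.fp_policy)
        return anns


def run_matrix(
    taggers: Sequence[TaggerSpec],
    corpora: Sequence[AnnotatedCorpus],
    eval_configs: Sequence[EvalConfig],
    idf: Optional[IdfTable] = None,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str, str], MatchResult]]:
    """All taggers × all corpora × all evaluation modes.

    Returns the league table (one row per cell; failed cells carry NaN
    metrics) and the MatchResult archive keyed by (tagger, corpus, mode).
    """
    rows = []
    results: Dict[Tuple[str, str, str], MatchResult] = {}
    prepared = {}
    for spec in taggers:
        prepared[spec.name] = spec.build()  # fail fast on bad specs
    for corpus in corpora:
        for spec in taggers:
            try:
                predictions = prepared[spec.name].tag(corpus)
            except Exception:
                logger.exception("tagging failed: %s on %s", spec.name, corpus.name)
                for cfg in eval_configs:
                    rows.append([corpus.name, spec.name, cfg.mode] + [None] * 6)
                continue
            for cfg in eval_configs:
                try:
                    res = match(corpus.gold, predictions, cfg, idf)
                    m = compute_metrics(res.tp, len(res.fp), len(res.fn))
                except Exception:
                    logger.exception(
                        "evaluation failed: %s on %s (%s)",
                        spec.name, corpus.name, cfg.mode,
                    )
                    rows.append([corpus.name, spec.name, cfg.mode] + [None] * 6)
                    continue
                results[(spec.name, corpus.name, cfg.mode)] = res
                rows.append([
                    corpus.name, spec.name, cfg.mode,
                    m.tp, m.fp, m.fn, m.precision, m.recall, m.f1,
                ])
                logger.info(
                    "%s x %s [%s]: tp=%d fp=%d fn=%d P=%.3f R=%.3f F1=%.3f",
                    spec.name, corpus.name, cfg.mode,
                    m.tp, m.fp, m.fn, m.precision, m.recall, m.f1,
                )
    table = pd.DataFrame(rows, columns=LEAGUE_COLUMNS)
    return table, results
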