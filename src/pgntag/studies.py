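"""Canned study designs on synthetic data.

These functions wire the generator, taggers and evaluation together into
the experiment shapes the package is built around: parameter recovery of
dictionary-tagger precision/recall against closed-form expectations, the
precision benefit of sequence-model false-positive filtering, and the
2 corpora × 2 taggers error-profile clustering design in which FN profiles
group by corpus while FP profiles group by tagger.

Every function is deterministic under its seed and returns plain numbers,
so the same routines back both the test suite and the results-reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

from .evaluate import EvalConfig, Metrics, compute_metrics, match
from .lexmatch import build_index, dictionary_tag, frequency_filter
from .model import Lexicon
from .profiles import ErrorProfile, build_profile, cluster_profiles, collect_errors
from .seqtag import TrainConfig, fp_filter, predict, train
from .synth import (
    SynthConfig,
    expected_dictionary_metrics,
    gen_background,
    gen_corpus,
    gen_lexicon,
)


def _measure(gold, pred) -> Metrics:
    res = match(gold, pred, EvalConfig(mode="exact"))
    return compute_metrics(res.tp, len(res.fp), len(res.fn))


def parameter_recovery(
    seed: int,
    n_docs: int = 200,
    mentions_per_doc_mean: float = 10.0,
) -> Dict[str, Dict[str, float]]:
    """Dictionary-tagger metrics on a corpus with known planted rates.

    The corpus plants roughly ``n_docs * mentions_per_doc_mean`` mentions
    at coverage 0.8, variant rate 0.25 and per-mention distractor rate
    0.2, giving closed-form expectations: exact-mode recall 0.6, alias
    recall 0.8, exact precision 0.75, and precision 1.0 after the
    background-frequency filter (the planted ambiguous terms outrank the
    reference term).  Returns measured and expected P/R per setting.
    """
    cfg = SynthConfig(
        seed=seed, n_docs=n_docs, sentences_per_doc=2,
        mentions_per_doc_mean=mentions_per_doc_mean,
        lexicon_size=400, coverage=0.8, variant_rate=0.25, ambiguity_rate=0.2,
    )
    lex = gen_lexicon(cfg)
    bg = gen_background(cfg, lex)
    gen = gen_corpus(cfg, lex, bg)
    expected = expected_dictionary_metrics(cfg)
    out: Dict[str, Dict[str, float]] = {"n_gold": {"value": len(gen.corpus.gold)}}
    for mode in ("exact", "alias"):
        idx = build_index(lex.lexicon, mode)
        tagged = [a for d in gen.corpus.documents for a in dictionary_tag(d, idx)]
        for filtered in (False, True):
            anns = frequency_filter(tagged, bg.freq) if filtered else tagged
            m = _measure(gen.corpus.gold, anns)
            e = expected[(mode, filtered)]
            out[f"{mode}{'_filtered' if filtered else ''}"] = {
                "precision": m.precision, "recall": m.recall,
                "expected_precision": e.precision, "expected_recall": e.recall,
            }
    return out


def fp_filter_replicate(seed: int) -> Dict[str, float]:
    """Train a sequence model and use it to clean dictionary output.

    One replicate: generate train/test corpora with context-learnable
    distractors, alias-tag the test corpus, filter with the model trained
    on the train corpus, measure precision/recall before and after.
    """
    cfg = SynthConfig(
        seed=seed, n_docs=30, sentences_per_doc=2, mentions_per_doc_mean=4.0,
        lexicon_size=150, coverage=0.8, variant_rate=0.25, ambiguity_rate=0.3,
    )
    lex = gen_lexicon(cfg)
    bg = gen_background(cfg, lex)
    tr = gen_corpus(replace(cfg, seed=seed * 2 + 1), lex, bg, name="train")
    te = gen_corpus(replace(cfg, seed=seed * 2 + 2), lex, bg, name="test")
    model = train(tr.corpus, TrainConfig(seed=seed, epochs=5))
    ml = [a for d in te.corpus.documents for a in predict(model, d)]
    idx = build_index(lex.lexicon, "alias")
    lex_anns = [a for d in te.corpus.documents for a in dictionary_tag(d, idx)]
    filtered = fp_filter(lex_anns, ml, policy="overlap")
    before = _measure(te.corpus.gold, lex_anns)
    after = _measure(te.corpus.gold, filtered)
    return {
        "precision_lex": before.precision, "recall_lex": before.recall,
        "precision_filtered": after.precision, "recall_filtered": after.recall,
        "n_lex": len(lex_anns), "n_filtered": len(filtered),
    }


@dataclass
class ProfileClusteringOutcome:
    fn_groups_by_corpus: bool
    fp_groups_by_tagger: bool


def profile_clustering_replicate(seed: int) -> ProfileClusteringOutcome:
    """The 2 corpora × 2 taggers error-profile design.

    Two dictionary taggers share a core lexicon but each carries private
    extra terms; both corpora plant all private terms as non-mention
    distractors and draw gold mentions from the shared core.  False
    negatives (missed novel terms) are corpus-specific, so FN profiles
    should cluster by corpus; false positives (each tagger's private
    distractor hits) are tagger-specific, so FP profiles should cluster by
    tagger.  Returns whether a 2-cut of each dendrogram recovers the
    expected grouping.
    """
    base = SynthConfig(
        seed=seed, n_docs=30, sentences_per_doc=2, mentions_per_doc_mean=4.0,
        lexicon_size=160, ambiguity_rate=0.0, coverage=0.75, variant_rate=0.2,
        oov_pool_size=20,
    )
    big = gen_lexicon(base)
    terms = big.mention_pool
    core, priv_a, priv_b = terms[:120], terms[120:140], terms[140:160]
    bg = gen_background(base, big)

    def sub_lexicon(name: str, keep: List[str]) -> Lexicon:
        keep_set = set(keep)
        return Lexicon(name=name, entries={
            cid: ts for cid, ts in big.lexicon.entries.items() if ts & keep_set
        })

    taggers = {
        "A": build_index(sub_lexicon("A", core + priv_a), "alias"),
        "B": build_index(sub_lexicon("B", core + priv_b), "alias"),
    }
    # interleave the private pools so the Zipf-weighted distractor sampling
    # gives BOTH taggers a structured (head-heavy) false-positive profile
    distractors = [t for pair in zip(priv_a, priv_b) for t in pair]
    corpora = {}
    for i, cname in enumerate(("c1", "c2")):
        ccfg = replace(base, seed=seed * 10 + i + 1, ambiguity_rate=0.6)
        corpora[cname] = gen_corpus(
            ccfg, big, bg, name=cname,
            mention_pool=core, extra_distractor_terms=distractors,
        ).corpus

    profiles: Dict[str, List[ErrorProfile]] = {"FP": [], "FN": []}
    for tname, idx in taggers.items():
        for cname, corpus in corpora.items():
            pred = [a for d in corpus.documents for a in dictionary_tag(d, idx)]
            res = match(corpus.gold, pred, EvalConfig(mode="exact"))
            for kind in ("FP", "FN"):
                profiles[kind].append(build_profile(
                    collect_errors(res, kind), cutoff=100,
                    normalizer=len(corpus.gold),
                    tagger=tname, corpus=cname, kind=kind,
                ))

    def grouped_by(kind: str, attr: str) -> bool:
        profs = profiles[kind]
        try:
            parts = cluster_profiles(profs).cut(2)
        except ValueError:
            return False
        partition = [{getattr(profs[i], attr) for i in part} for part in parts]
        return all(len(vals) == 1 for vals in partition)

    return ProfileClusteringOutcome(
        fn_groups_by_corpus=grouped_by("FN", "corpus"),
        fp_groups_by_tagger=grouped_by("FP", "tagger"),
    )
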