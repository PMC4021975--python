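"""IDF weighting, soft span matching, alternatives, metric identities."""

import itertools
import math
import random

import pytest

from pgntag.evaluate import (
    EvalConfig,
    IdfTable,
    build_idf,
    compute_metrics,
    cosine_similarity,
    evaluate_with_alternatives,
    match,
)
from pgntag.model import Annotation, Document


def ann(start, end, surface, doc="d"):
    return Annotation(doc_id=doc, start=start, end=end, surface=surface)


class TestIdf:
    def test_formula_values(self):
        idf = IdfTable(n_docs=100, doc_freqs={"common": 100, "rare": 1})
        assert idf.idf("common") == 0.0
        assert idf.idf("rare") == pytest.approx(math.log(100))
        assert idf.idf("unseen") == pytest.approx(math.log(200))

    def test_monotone_in_doc_freq(self):
        idf = IdfTable(n_docs=50, doc_freqs={f"t{d}": d for d in range(1, 51)})
        vals = [idf.idf(f"t{d}") for d in range(1, 51)]
        assert vals == sorted(vals, reverse=True)

    def test_build_from_documents(self):
        docs = [Document("a", "p53 binds dna"), Document("b", "dna only")]
        idf = build_idf(docs)
        assert idf.n_docs == 2
        assert idf.idf("dna") == 0.0
        assert idf.idf("p53") == pytest.approx(math.log(2))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            build_idf([])


HZF_IDF = IdfTable(n_docs=1, doc_freqs={})


class _FixedIdf(IdfTable):
    def __init__(self, table):
        super().__init__(n_docs=1, doc_freqs={})
        self.table = table

    def idf(self, token):
        return self.table[token]


class TestCosine:
    def test_identical_strings(self):
        idf = _FixedIdf({"p53": 3.0})
        assert cosine_similarity("p53", "p53", idf) == pytest.approx(1.0)

    def test_disjoint_strings(self):
        idf = _FixedIdf({"a": 2.0, "b": 3.0})
        assert cosine_similarity("a", "b", idf) == 0.0

    def test_low_information_tail_passes_threshold(self):
        idf = _FixedIdf({"hzf": 10.0, "7": 10.0, "protein": 0.5})
        sim = cosine_similarity("HZF-7", "HZF-7 protein", idf)
        assert sim == pytest.approx(200.0 / math.sqrt(200.0 * 200.25))
        assert sim > 0.98

    def test_zero_norm_conventions(self):
        idf = _FixedIdf({"the": 0.0, "of": 0.0, "p53": 5.0})
        assert cosine_similarity("the", "the", idf) == 1.0
        assert cosine_similarity("the", "of", idf) == 0.0
        assert cosine_similarity("the", "p53", idf) == 0.0

    def test_symmetry(self):
        rng = random.Random(0)
        words = ["p53", "ras", "protein", "the", "kinase", "alpha"]
        idf = IdfTable(n_docs=100, doc_freqs={"the": 100, "protein": 90,
                                              "p53": 3, "ras": 5, "kinase": 20})
        for _ in range(200):
            a = " ".join(rng.choices(words, k=rng.randint(1, 4)))
            b = " ".join(rng.choices(words, k=rng.randint(1, 4)))
            assert cosine_similarity(a, b, idf) == pytest.approx(
                cosine_similarity(b, a, idf), abs=1e-12
            )


class TestMatch:
    def test_exact_identical_span(self):
        res = match([ann(0, 5, "ABCDE")], [ann(0, 5, "ABCDE")],
                    EvalConfig(mode="exact"))
        assert (res.tp, len(res.fp), len(res.fn)) == (1, 0, 0)

    def test_cos98_recovers_boundary_extension(self):
        idf = _FixedIdf({"hzf": 10.0, "7": 10.0, "protein": 0.5})
        gold = [ann(10, 15, "HZF-7")]
        pred = [ann(10, 23, "HZF-7 protein")]
        exact = match(gold, pred, EvalConfig(mode="exact"))
        assert (exact.tp, len(exact.fp), len(exact.fn)) == (0, 1, 1)
        soft = match(gold, pred, EvalConfig(mode="cos98"), idf)
        assert (soft.tp, len(soft.fp), len(soft.fn)) == (1, 0, 0)

    def test_overlap_required_by_default(self):
        idf = _FixedIdf({"p53": 5.0})
        res = match([ann(0, 3, "p53")], [ann(40, 43, "p53")],
                    EvalConfig(mode="cos98"), idf)
        assert res.tp == 0
        res2 = match([ann(0, 3, "p53")], [ann(40, 43, "p53")],
                     EvalConfig(mode="cos98", require_overlap=False), idf)
        assert res2.tp == 1

    def test_one_to_one_bookkeeping(self):
        gold = [ann(0, 3, "p53"), ann(10, 13, "ras")]
        pred = [ann(0, 3, "p53"), ann(0, 3, "p53", )]
        res = match(gold, pred, EvalConfig(mode="exact"))
        assert res.tp + len(res.fn) == len(gold)
        assert res.tp + len(res.fp) == len(pred)
        assert res.tp == 1

    def test_greedy_equals_bruteforce_on_small_instances(self):
        rng = random.Random(42)
        idf = IdfTable(n_docs=1000, doc_freqs={"protein": 1000, "the": 1000})
        words = ["abc", "xyz", "p53", "ras", "wnt", "kin", "protein"]
        agree = 0
        trials = 200
        for _ in range(trials):
            gold, pred = [], []
            pos = 0
            for _ in range(rng.randint(1, 6)):
                w = " ".join(rng.choices(words, k=rng.randint(1, 2)))
                gold.append(ann(pos, pos + len(w), w))
                pos += len(w) + 1
            for g in gold:
                if rng.random() < 0.8:
                    delta = rng.choice([0, 0, 1])
                    surf = g.surface + (" protein" if rng.random() < 0.3 else "")
                    pred.append(ann(g.start, g.start + len(surf) - delta or 1, surf))
            cfg = EvalConfig(mode="cos98")
            res = match(gold, pred, cfg, idf)
            best = _bruteforce_tp(gold, pred, cfg, idf)
            agree += res.tp == best
            assert res.tp <= best
        assert agree / trials >= 0.99


def _bruteforce_tp(gold, pred, cfg, idf):
    """Maximum one-to-one matching by exhaustive assignment."""
    edges = [
        [j for j, p in enumerate(pred)
         if g.doc_id == p.doc_id
         and (not cfg.require_overlap or g.overlaps(p))
         and cosine_similarity(g.surface, p.surface, idf) > cfg.threshold]
        for g in gold
    ]

    def rec(i, used):
        if i == len(edges):
            return 0
        best = rec(i + 1, used)
        for j in edges[i]:
            if j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


class TestAlternatives:
    """BC2-style alternative-span credit, modelled on the printed example:
    main span (11,31) "secretory HIantibodies" with alternatives
    (11,21) "secretory HI", (20,21) "HI", (20,31) "HI antibodies"."""

    GOLD = [ann(11, 31, "secretory HIantibodies", doc="P00027967A0207")]
    ALTS = [
        ann(11, 21, "secretory HI", doc="P00027967A0207"),
        ann(20, 21, "HI", doc="P00027967A0207"),
        ann(20, 31, "HI antibodies", doc="P00027967A0207"),
    ]
    PRED = [ann(20, 21, "HI", doc="P00027967A0207")]

    def test_ignore_policy_counts_fp_and_fn(self):
        m = evaluate_with_alternatives(
            self.GOLD, self.ALTS, self.PRED,
            EvalConfig(mode="exact", alternatives_policy="ignore"))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_tier1_needs_matched_main(self):
        m = evaluate_with_alternatives(
            self.GOLD, self.ALTS, self.PRED,
            EvalConfig(mode="exact", alternatives_policy="tier1"))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_tier2_credits_unmatched_gene(self):
        m = evaluate_with_alternatives(
            self.GOLD, self.ALTS, self.PRED,
            EvalConfig(mode="exact", alternatives_policy="tier1+tier2"))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_no_alternatives_policies_identical(self):
        for policy in ("ignore", "tier1", "tier1+tier2"):
            m = evaluate_with_alternatives(
                self.GOLD, [], self.PRED,
                EvalConfig(mode="exact", alternatives_policy=policy))
            assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_gene_credited_at_most_once(self):
        pred = [ann(11, 31, "secretory HIantibodies", doc="P00027967A0207"),
                ann(20, 21, "HI", doc="P00027967A0207"),
                ann(11, 21, "secretory HI", doc="P00027967A0207")]
        m = evaluate_with_alternatives(
            self.GOLD, self.ALTS, pred,
            EvalConfig(mode="exact", alternatives_policy="tier1+tier2"))
        # main match + one alternative credit; third prediction stays FP
        assert (m.tp, m.fp, m.fn) == (2, 1, 0)

    def test_unknown_record_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            evaluate_with_alternatives(
                self.GOLD, [ann(0, 2, "xx", doc="other")], self.PRED,
                EvalConfig(mode="exact"))


class TestMetrics:
    def test_direct_formula(self):
        m = compute_metrics(3, 1, 2)
        assert (m.precision, m.recall) == (0.75, 0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_zero_conventions(self):
        m = compute_metrics(0, 0, 10)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert compute_metrics(5, 0, 0).f1 == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0)

    def test_identities_on_grid(self):
        for tp, fp, fn in itertools.product(range(6), repeat=3):
            m = compute_metrics(tp, fp, fn)
            p, r = m.precision, m.recall
            assert min(p, r) - 1e-12 <= m.f1 <= max(p, r) + 1e-12
            if p + r > 0:
                assert m.f1 == pytest.approx(2 * p * r / (p + r))
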