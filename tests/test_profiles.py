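"""Error profiles, correlation, complete-linkage clustering, categorization."""

import itertools

import numpy as np
import pytest

from pgntag.evaluate import EvalConfig, MatchResult
from pgntag.model import Annotation, Lexicon
from pgntag.profiles import (
    CategoryResources,
    ErrorCategory,
    NoVarianceError,
    Relevance,
    RELEVANCE_OF,
    aggregate_top_errors,
    build_profile,
    categorize_error,
    cluster_profiles,
    collect_errors,
    default_resources,
    profile_correlation,
)


def ann(surface, doc="d", start=0):
    return Annotation(doc_id=doc, start=start, end=start + len(surface),
                      surface=surface)


def result(fp=(), fn=()):
    return MatchResult(tp_pairs=[], fp=[ann(s, start=i * 50) for i, s in enumerate(fp)],
                       fn=[ann(s, start=i * 50) for i, s in enumerate(fn)],
                       config=EvalConfig())


def profile(counts, **kw):
    kw.setdefault("normalizer", 100)
    return build_profile(counts, **kw)


class TestCollectAndBuild:
    def test_multiset_with_multiplicity(self):
        errs = collect_errors(result(fp=["kinases", "kinases", "T3"]), "FP")
        assert errs == {"kinases": 2, "T3": 1}

    def test_fn_kind_ignores_fp(self):
        errs = collect_errors(result(fp=["a"], fn=["b"]), "FN")
        assert errs == {"b": 1}

    def test_perfect_result_empty(self):
        assert collect_errors(result(), "FP") == {}

    def test_topn_and_ties(self):
        p = profile({"aa": 5, "bb": 3, "cc": 1}, cutoff=2)
        assert p.entries == [("aa", 5), ("bb", 3)]
        p = profile({"aa": 2, "ab": 2}, cutoff=1)
        assert p.entries == [("aa", 2)]

    def test_fewer_than_cutoff_retained(self):
        p = profile({"aa": 1}, cutoff=100)
        assert p.entries == [("aa", 1)]

    def test_normalizer_validation(self):
        with pytest.raises(ValueError):
            build_profile({"a": 1}, normalizer=0)

    def test_rates(self):
        p = profile({"aa": 5}, normalizer=50)
        assert p.rates() == {"aa": 0.1}


class TestCorrelation:
    def test_self_correlation(self):
        p = profile({"a": 3, "b": 2, "c": 1})
        assert profile_correlation(p, p) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        p1 = profile({"a": 1, "b": 2, "c": 3})
        p2 = profile({"a": 3, "b": 2, "c": 1})
        assert profile_correlation(p1, p2) == pytest.approx(-1.0)

    def test_union_alignment_matches_direct_formula(self):
        p1 = profile({"a": 4, "b": 1})
        p2 = profile({"b": 2, "c": 5})
        # aligned over {a,b,c}: (4,1,0) vs (0,2,5)
        expected = np.corrcoef([4, 1, 0], [0, 2, 5])[0, 1]
        assert profile_correlation(p1, p2) == pytest.approx(float(expected))

    def test_no_variance_is_distinct_outcome(self):
        flat = profile({"a": 2, "b": 2})
        varied = profile({"a": 1, "b": 3})
        with pytest.raises(NoVarianceError):
            profile_correlation(flat, varied)


def _bruteforce_complete_linkage(profiles):
    """Oracle: recompute max inter-cluster distance from scratch each merge."""
    n = len(profiles)
    d0 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d0[(i, j)] = 1.0 - profile_correlation(profiles[i], profiles[j])

    def leaf_dist(a, b):
        return d0[(a, b) if a < b else (b, a)]

    clusters = {i: {i} for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = max(leaf_dist(x, y) for x in clusters[a] for y in clusters[b])
            if best is None or (dist, a, b) < best:
                best = (dist, a, b)
        dist, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        heights.append(dist)
        next_id += 1
    return heights


class TestClustering:
    def rand_profiles(self, rng, n=6, keys=15):
        out = []
        for i in range(n):
            counts = {f"w{j}": int(rng.integers(1, 40)) for j in range(keys)}
            out.append(profile(counts, tagger=f"t{i}"))
        return out

    def test_identical_profiles_merge_at_zero(self):
        p1 = profile({"a": 3, "b": 1}, tagger="x")
        p2 = profile({"a": 3, "b": 1}, tagger="y")
        p3 = profile({"a": 1, "b": 9}, tagger="z")
        dend = cluster_profiles([p1, p2, p3])
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[0][2] == pytest.approx(0.0)

    def test_cut_recovers_planted_pairs(self):
        pa = {"a": 9, "b": 1, "c": 2, "d": 1}
        pb = {"a": 1, "b": 2, "e": 9, "f": 6}
        profs = [profile(pa, tagger="a1"), profile(pa, tagger="a2"),
                 profile(pb, tagger="b1"), profile(pb, tagger="b2")]
        dend = cluster_profiles(profs)
        parts = dend.cut(2)
        assert sorted(map(sorted, parts)) == [[0, 1], [2, 3]]

    def test_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            profs = self.rand_profiles(rng, n=int(rng.integers(3, 8)))
            dend = cluster_profiles(profs)
            oracle = _bruteforce_complete_linkage(profs)
            assert [m[2] for m in dend.merges] == pytest.approx(oracle)

    def test_heights_match_scipy(self):
        import scipy.cluster.hierarchy as sch
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        profs = self.rand_profiles(rng, n=7)
        n = len(profs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = 1 - profile_correlation(profs[i], profs[j])
        Z = sch.linkage(squareform(D), method="complete")
        dend = cluster_profiles(profs)
        assert [m[2] for m in dend.merges] == pytest.approx(list(Z[:, 2]))

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            profs = self.rand_profiles(rng)
            hs = [m[2] for m in cluster_profiles(profs).merges]
            assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_undefined_pair_names_offenders(self):
        flat = profile({"a": 2, "b": 2}, tagger="flat")
        varied = profile({"a": 1, "b": 3}, tagger="var")
        with pytest.raises(NoVarianceError, match="flat"):
            cluster_profiles([flat, varied])

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            cluster_profiles([profile({"a": 1, "b": 2})])


TABLE4_EXPECTED = [
    ("N", ErrorCategory.C1),
    ("T3", ErrorCategory.C2),
    ("Ras", ErrorCategory.A_PG),
    ("c-fos", ErrorCategory.A_PG),
    ("Wnt", ErrorCategory.A_PG),
    ("p53 protein", ErrorCategory.EA_PG),
    ("Ras gene", ErrorCategory.EA_PG),
    ("Src family", ErrorCategory.EA_PG),
    ("p53 mutations", ErrorCategory.XA_PG),
    ("E-cadherin", ErrorCategory.PGT),
    ("beta-catenin", ErrorCategory.PGT),
    ("glucocorticoid receptor", ErrorCategory.PGT),
    ("prion", ErrorCategory.BMT),
    ("IgM", ErrorCategory.BMT),
    ("Plasma", ErrorCategory.GE),
]


class TestCategorization:
    @pytest.mark.parametrize("surface,expected", TABLE4_EXPECTED)
    def test_documented_assignments(self, surface, expected):
        assert categorize_error(surface, default_resources()) is expected

    def test_lexicon_precedence_over_general_english(self):
        res = CategoryResources(
            lexicon=Lexicon(name="l", entries={"G": {"plasma"}}),
            general_english={"plasma"},
        )
        assert categorize_error("plasma", res) is ErrorCategory.A_PG

    def test_unknown_with_empty_resources(self):
        res = CategoryResources(lexicon=Lexicon(name="e", entries={}))
        assert categorize_error("xyzzyq", res) is ErrorCategory.UNK

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            categorize_error("  ", default_resources())

    def test_total_over_generated_errors(self, small_world):
        _cfg, lex, _bg, gen = small_world
        res = default_resources()
        for a in gen.corpus.gold[:100]:
            assert categorize_error(a.surface, res) in ErrorCategory


class TestAggregate:
    def test_rates_and_rollup(self):
        fp = ["plasma"] * 30
        table = aggregate_top_errors(result(fp=fp), default_resources(),
                                     kind="FP", k=15, normalizer=600)
        assert table.counts[ErrorCategory.GE] == 30
        assert table.rates[ErrorCategory.GE] == pytest.approx(0.05)
        assert table.rollup_rates[Relevance.ARTEFACT] == pytest.approx(0.05)

    def test_empty_errors_all_zero(self):
        table = aggregate_top_errors(result(), default_resources(),
                                     kind="FP", normalizer=10)
        assert all(v == 0 for v in table.counts.values())

    def test_rollup_conserves_counts(self):
        fp = ["N", "T3", "Ras", "p53 protein", "p53 mutations",
              "E-cadherin", "prion", "Plasma", "Wnt", "IgM"] * 3
        table = aggregate_top_errors(result(fp=fp), default_resources(),
                                     kind="FP", k=15, normalizer=100)
        assert sum(table.rollup_counts.values()) + table.unk_count == sum(
            table.counts.values()
        ) + table.unk_count
        for rel in Relevance:
            members = [c for c, r in RELEVANCE_OF.items() if r is rel]
            assert table.rollup_counts[rel] == sum(table.counts[c] for c in members)
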