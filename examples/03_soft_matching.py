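"""Exact vs cos98 evaluation, and alternative-annotation credit.

Shows how IDF-weighted cosine similarity forgives a boundary that differs
only by a low-information token ("protein"), and how the alternative
gene-list policies credit a prediction that hits an acceptable sub-span.
"""

from pgntag import (
    Annotation,
    EvalConfig,
    IdfTable,
    compute_metrics,
    cosine_similarity,
    evaluate_with_alternatives,
    match,
)

idf = IdfTable(n_docs=1000, doc_freqs={"protein": 950, "hzf": 2, "7": 40})
a, b = "HZF-7", "HZF-7 protein"
print(f"cos({a!r}, {b!r}) = {cosine_similarity(a, b, idf):.5f}  (> 0.98)")

gold = [Annotation("d", 10, 15, "HZF-7")]
pred = [Annotation("d", 10, 23, "HZF-7 protein")]
for mode in ("exact", "cos98"):
    r = match(gold, pred, EvalConfig(mode=mode), idf)
    m = compute_metrics(r.tp, len(r.fp), len(r.fn))
    print(f"{mode:5s}: tp={m.tp} fp={m.fp} fn={m.fn} F1={m.f1:.2f}")
# exact matching scores the extended boundary as one FP plus one FN;
# cos98 pairs the two spans because they differ only by "protein"

# alternative spans: the main annotation is missed but the prediction
# hits an acceptable alternative of the same gene record
gold = [Annotation("r1", 11, 31, "secretory HIantibodies")]
alts = [Annotation("r1", 11, 21, "secretory HI"),
        Annotation("r1", 20, 21, "HI"),
        Annotation("r1", 20, 31, "HI antibodies")]
pred = [Annotation("r1", 20, 21, "HI")]
for policy in ("ignore", "tier1", "tier1+tier2"):
    m = evaluate_with_alternatives(
        gold, alts, pred, EvalConfig(mode="exact", alternatives_policy=policy))
    print(f"{policy:12s}: tp={m.tp} fp={m.fp} fn={m.fn}")
# tier1 only credits alternatives of genes whose main span was found, so
# the credit appears only under tier1+tier2 here
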