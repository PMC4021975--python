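"""Error profiles: clustering and categorization.

Runs the 2 corpora × 2 taggers design and clusters the false-negative and
false-positive profiles; FN profiles group by corpus (misses are dictated
by the corpus's annotation content) while FP profiles group by tagger
(spurious hits are dictated by the tagger's resources).  Then categorizes
a handful of error surfaces with the packaged term lists.
"""

from pgntag import categorize_error, default_resources
from pgntag.studies import profile_clustering_replicate

outcome = profile_clustering_replicate(seed=3)
print("FN profiles cluster by corpus:", outcome.fn_groups_by_corpus)
print("FP profiles cluster by tagger:", outcome.fp_groups_by_tagger)

res = default_resources()
for surface in ("N", "T3", "Ras", "p53 protein", "p53 mutations",
                "E-cadherin", "prion", "Plasma"):
    print(f"{surface!r:18s} -> {categorize_error(surface, res).value}")
# 1C/2C are length artifacts; a-PG and PGT (acronym and long-form names)
# are the Core errors a tagger must not make; ea-PG/xa-PG are head-noun
# extensions with preserved/modified meaning; BMT and GE are biomedical
# and general-English vocabulary wrongly tagged
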