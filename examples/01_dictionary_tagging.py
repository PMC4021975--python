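"""Dictionary tagging with alias matching and frequency disambiguation.

Builds a tiny lexicon, tags a sentence in exact and alias mode, then
removes a too-common word with the background-frequency filter.
"""

from pgntag import (
    Document,
    FrequencyList,
    Lexicon,
    build_index,
    dictionary_tag,
    frequency_filter,
    normalize_term,
)

lexicon = Lexicon(name="demo", entries={
    "G1": {"HZF-7"},
    "G2": {"insulin receptor"},
    "G3": {"factor"},          # also a common English word
})

doc = Document("d1", "The insulin receptor binds HZF/7 and factor levels rise.")

for mode in ("exact", "alias"):
    anns = dictionary_tag(doc, build_index(lexicon, mode))
    print(f"{mode:5s} mode: {[(a.surface, a.span) for a in anns]}")
# exact mode misses HZF/7 because the separator differs from the lexicon
# form HZF-7; alias mode normalizes "- / " separators, initial case and
# plural "s", so HZF-7 == HZF/7 == hzf 7:
print("alias keys:", {t: normalize_term(t, "alias") for t in ("HZF-7", "HZF/7")})

# background frequencies: "factor" occurs far more often than the
# reference term "insulin", so tagged occurrences of it are unspecific
bnc = FrequencyList(counts={"insulin": 10, "factor": 4000, "the": 90000})
anns = dictionary_tag(doc, build_index(lexicon, "alias"))
kept = frequency_filter(anns, bnc, ref_term="insulin")
print("before filter:", [a.surface for a in anns])
print("after  filter:", [a.surface for a in kept])
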