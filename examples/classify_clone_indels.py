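"""Classify indels in a hand-built clone alignment.

Three rulings on one tiny clone family: a deletion inside an AA tract
carried by a single member of a three-member clone is a sequencing
artifact; the same deletion in a one-member clone cannot be judged and
stays uncertain; a low-quality point mutation inside the AID hotspot
AACA is kept because the deaminase plausibly put it there.
"""

from igclean import ClonalAlignment, IndelConfig, classify_sequence

config = IndelConfig(min_share=2, min_hpt_len=2, min_qual=10)

family = ClonalAlignment("family", "GL", "CCAAACC",
                         [("seq1", "CCA-ACC"), ("seq2", "CCAAACC"), ("seq3", "CCAAACC")])
v = classify_sequence("seq1", family, config=config)
print(f"unique deletion in AAA tract, clone of 3 -> {v.verdict}")

orphan = ClonalAlignment("orphan", "GL", "CCAAACC", [("seq1", "CCA-ACC")])
v = classify_sequence("seq1", orphan, config=config)
print(f"same deletion, clone of 1            -> {v.verdict}")

hotspot = ClonalAlignment("hotspot", "GL", "GGAACAGG",
                          [("seq1", "GGATCAGG"), ("seq2", "GGAACAGG"), ("seq3", "GGAACAGG")])
quals = [40, 40, 40, 8, 40, 40, 40, 40]  # the mutated base was called at Q8
v = classify_sequence("seq1", hotspot, quals, config)
print(f"Q8 mutation inside AACA motif         -> {v.verdict} (kept)")
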