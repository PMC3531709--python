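"""Diagnostics for a MID tag set: how distinguishable are the barcodes?

Demultiplexing tolerates boundary damage by matching only the inner
(gene-proximal) end of a tag, so the shortest inner fragment that still
identifies every tag unambiguously — in either orientation — decides the
safe value of the minimal-MID-length parameter.
"""

from igclean import BASIC_MID_SET, min_distinguishing_inner_length
from igclean.midtags import min_pairwise_hamming

print("tag set:")
for i, mid in enumerate(BASIC_MID_SET, 1):
    print(f"  MID{i}  {mid}")

d = min_pairwise_hamming(BASIC_MID_SET)
k = min_distinguishing_inner_length(BASIC_MID_SET)
print(f"\nminimum pairwise Hamming distance : {d}")
print(f"minimal distinguishing inner length: {k}")
print(f"\nAny two tags differ at >= {d} of 10 positions, and {k} consecutive")
print("gene-proximal bases suffice to name a tag even when the sequencer")
print("damaged its outer end — so 'Minimal MID length' can be set to", k)
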