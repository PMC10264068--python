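"""Locate the anticodon arm in a tRNA gene sequence.

Builds a small tRNA-like sequence with a planted anticodon arm, then
locates the 5-bp stem / 7-nt loop and prints the loop in the fixed
coordinate frame (loop indices 0-6 = tRNA positions 32-38, anticodon at
indices 2-4).
"""

from phagetrna import find_anticodon_arm

# 4-nt flank | 5-bp stem | 7-nt loop (anticodon GCT at loop 2-4) | stem | flank
sequence = "AAAA" + "GGCGC" + "CTGCTAA" + "GCGCC" + "AAAA"

arm = find_anticodon_arm(sequence, anticodon_hint="GCT")
print(f"loop start      : {arm.loop_start} (0-based index in the gene)")
print(f"anticodon loop  : {arm.loop}")
print(f"anticodon       : {arm.anticodon} (loop indices 2-4)")
print(f"stem pairing    : {arm.pairing_count}/5 "
      "(Watson-Crick or G:T wobble)")

# The loop string is the window every nuclease cleavage bond refers to:
# bond b cuts between loop positions b and b+1, so bond 3 for this gene
# would cut between the C and the T of the GCT anticodon.
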