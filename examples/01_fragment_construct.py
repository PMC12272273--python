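"""Dice a dsRNA construct into its siRNA-sized fragments.

Builds a 398-nt construct (the classic geometry: 398 - 21 + 1 = 378 unique
21-mers when no window repeats), fragments it on the sense strand, and
expands to both siRNA strands.
"""

from offscreen import dice, enumerate_orientations, random_construct

construct = random_construct(398, rng_seed=1, distinct_kmers=True)
sense = dice(construct, k=21)
both = enumerate_orientations(sense, policy="both")

print(f"construct: {construct.identifier}, {len(construct)} nt")
print(f"unique sense 21-mers: {len(sense)}")
print(f"with antisense strands: {len(both)}")
print(f"first fragment: {sense[0].fragment_id} -> {sense[0].residues}")

# Every 21-nt window of the construct can become an siRNA guide; 378 is the
# number of distinct guides the screen must check against each database.
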