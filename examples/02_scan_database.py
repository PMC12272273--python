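"""Scan one fragment against a transcript with the mismatch-tolerant search.

Plants a copy of the fragment with a single substitution at guide position
10 inside a random transcript, then shows the statistics the filter funnel
reads: total identities, mismatch positions (guide coordinates), the longest
perfect run and the longest stretch holding at most two mismatches.
"""

import numpy as np

from offscreen import NucleotideSequence, scan
from offscreen.fragmentation import SirnaFragment

rng = np.random.default_rng(4)
bases = "ACGT"
frag_seq = "".join(bases[i] for i in rng.integers(0, 4, size=21))
fragment = SirnaFragment(parent_id="demo", start=1, k=21, residues=frag_seq,
                         orientation="sense", fragment_index=0)

site = list(frag_seq)
site[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[9]]  # guide pos 10
backbone = "".join(bases[i] for i in rng.integers(0, 4, size=500))
transcript = NucleotideSequence(
    "tx1", backbone[:200] + "".join(site) + backbone[221:])

for hit in scan(fragment, transcript, min_identities=16):
    print(f"placement {hit.t_start}-{hit.t_end} ({hit.target_strand}): "
          f"{hit.identities}/21 identities, "
          f"mismatches at {list(hit.mismatch_positions) or 'none'}, "
          f"longest perfect run {hit.longest_perfect_run}, "
          f"best stretch with <=2 mismatches {hit.best_near_perfect}")

# A single mid-fragment substitution leaves 20/21 identities and splits the
# perfect run (11 nt at best) while the 2-mismatch stretch still spans all 21.
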