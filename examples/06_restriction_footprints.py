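"""Read out DSB end structures from restriction-enzyme-style cuts.

Simulates cuts with known overhangs: blunt cuts leave abutting read stacks,
5' overhangs overlap after end-repair fill-in, 3' overhangs leave a gap.
The footprint (signed overhang length) is recovered exactly from the stack
geometry.
"""

from scissionkit import breakio, scission, simdata
from scissionkit._seq import random_dna

import numpy as np

rng = np.random.default_rng(13)
genome = {"chr1": random_dna(rng, 10_000)}

print("overhang  stack geometry          inferred")
for overhang, label in [(0, "blunt, stacks abut"), (4, "5' overhang, overlap 4"),
                        (2, "5' overhang, overlap 2"), (-2, "3' overhang, gap 2"),
                        (-3, "3' overhang, gap 3")]:
    ends = simdata.simulate_restriction_fixture(
        {"chrom": "chr1", "position": 5000, "overhang_signed_length": overhang},
        genome, depth=30, seed=13,
    )
    pile = breakio.dedup_ends(ends, max_umi_mismatch=-1)
    prox = int(pile.loc[pile["strand"] == "+", "pos0"].iloc[0])
    dist = int(pile.loc[pile["strand"] == "-", "pos0"].iloc[0])
    inferred = scission.footprint_from_stacks(prox, dist)
    print(f"{overhang:+8d}  {label:22s}  {inferred:+d}")
# positive = 5' overhang (filled in toward the cut, reads overlap),
# negative = 3' overhang (chewed back, reads gap), zero = blunt
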