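"""Triage a pathogenic 1-nt deletion for templated-insertion correction.

Builds a toy coding gene, deletes one CDS base (a frameshift), enumerates
guides on the deletion allele whose NGG PAM lies within 4 nt of the
deletion, determines the templated +1 insertion outcome (the protospacer
position-17 base duplicated at the blunt boundary), checks frame and
protein recovery, ranks candidates by predicted staggeredness, and prints
the T7 construct for the best guide.
"""

import numpy as np
import pandas as pd

from scissionkit import reframe, scissmodel, simdata
from scissionkit.reframe import Transcript
from scissionkit._seq import random_dna

rng = np.random.default_rng(11)
flank, cds_len = 80, 120
# try random backbones until the deletion allele offers an NGG placement
for attempt in range(100):
    seq = (random_dna(rng, flank) + "ATG" + random_dna(rng, cds_len - 3)
           + random_dna(rng, flank))
    genome = {"chr1": seq}
    tx = Transcript("tx", "chr1", "+", [(flank, flank + cds_len)])
    d = int(rng.integers(flank + 3, flank + cds_len - 3))
    deletion = {"chrom": "chr1", "deleted_pos0": d, "deleted_base": seq[d]}
    placements = reframe.place_guides(deletion, genome)
    if len(placements):
        break

print(f"deletion at chr1:{d} ({deletion['deleted_base']}) -> "
      f"{len(placements)} guide placement(s) on the deletion allele")

rows = []
for _, pl in placements.iterrows():
    outcome = reframe.templated_insertion_outcome(pl, deletion, tx, genome)
    rows.append({**pl.to_dict(), **outcome})
candidates = pd.DataFrame(rows)

instances = simdata.make_rule_instances(1000, seed=12, noise_sd=0.5)
model, _ = scissmodel.train_blunt_model(instances, flavor="reduced", seed=12, n_trees=200)
ranked, report = reframe.rank_candidates(candidates, {"cas9": model})
print(ranked[["strand", "offset", "insert_base", "frame_restored",
              "protein_restored", "rate_cas9", "class_cas9"]]
      .round(2).to_string(index=False))
# frame is restored whenever the +1 insertion lands inside the CDS; the
# protein is recovered only when codon degeneracy absorbs the inserted base
print(f"\nhighly staggered candidates (log2 rate <= -2): {report['cas9']}")
best = ranked.iloc[0]
print("T7 construct for the top-ranked guide:")
print(reframe.design_t7_construct(best["protospacer"]))
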