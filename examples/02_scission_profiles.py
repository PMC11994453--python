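"""Quantify blunt vs staggered scission at nominated target sites.

Reuses the simulated run from example 01 and computes, per site, the
boundary-label histogram of the PAM-proximal break signal, the blunt rate
in both forms (raw fraction and pseudocounted log2 ratio), the
blunt/middle/staggered class, and the pooled overhang-length distribution.
"""

from scissionkit import breakio, scission, simdata

cfg = simdata.SimConfig(seed=1, chrom_length=50_000, n_guides=5, offtargets_per_guide=3)
genome, truth = simdata.gen_genome(cfg)
ends = simdata.simulate_break_ends(truth, genome, cfg)
pileup = breakio.dedup_ends(breakio.filter_mapq(ends))

profiles = scission.profile_targets(truth.sites, pileup, min_proximal=16)
print(profiles[["start", "strand", "n_mismatches", "proximal_total",
                "blunt_fraction", "log2_blunt_rate", "scission_class"]]
      .head(8).round(3).to_string(index=False))
# blunt_fraction = share of proximal molecules exactly at boundary label 17;
# the log2 form is the model response; classes use 1/3 and 2/3 staggered cuts

dist = scission.overhang_distribution(profiles)
print("\npooled end-structure distribution:")
print(dist.round(3).to_string())
# blunt = abutting read stacks; 1-3 nt entries are 5' overhangs read out as
# stack overlaps after the end-repair fill-in

table, fit = scission.bluntrate_vs_mismatch(profiles)
print(f"\nblunt rate vs mismatch count: slope={fit['slope']:.3f} "
      f"Pearson r={fit['pearson_r']:.3f}")
# the simulator lowers the blunt fraction per planted mismatch, so the
# recovered trend is negative
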