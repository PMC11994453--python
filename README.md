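# scissionkit

Analysis toolkit for CRISPR–Cas9 double-strand-break (DSB) end-capture
sequencing: it nominates on- and off-target cleavage sites from
strand-resolved read-end pileups, quantifies each site's *scission profile*
(blunt vs staggered cuts and overhang lengths), models the blunt rate from
protospacer sequence with gradient-boosted trees, predicts allele-specific
scission changes at SNVs, and triages pathogenic 1-nt deletions that a
templated +1 insertion could correct. A first-class synthetic-data module
generates genomes and break-end libraries with known ground truth, so every
stage is testable end to end without any external download.

It is written for genome-engineering researchers who work with DSB
end-capture data (in-vitro RNP digestion of genomic DNA followed by
end repair, UMI-tagged adaptor ligation and sequencing) and for method
developers who need a reference implementation of scission-profile
analytics.

## The model in brief

Protospacer positions are numbered 1 (PAM-distal) to 20 (PAM-adjacent). A
break boundary label *b* ∈ {14..20} names the boundary between positions
*b* and *b*+1; the canonical blunt cut sits at *b* = 17, three nucleotides
upstream of the NGG PAM. Because library end repair fills 5′ overhangs in
toward the PAM, the PAM-distal read end always maps at the blunt boundary,
while the PAM-proximal end maps at *b* = 17 for a blunt cut and at
*b* = 17 − *n* for an *n*-nt 5′ overhang — so the overlap (or, for
restriction-style 3′ overhangs, the gap) between the two read stacks is a
direct footprint of the cut structure.

For a site with proximal counts *c₁₄..c₂₀* the blunt rate is reported two
ways:

* fraction: *f* = *c₁₇* / Σ*c₁₄..₂₀*
* log2 ratio: log₂((*c₁₇* + 1) / (Σ*c₁₄..₁₆,₁₈..₂₀* + 1))

Without pseudocounts the two obey ratio = log₂(*f*/(1 − *f*)): 50% blunt ⇔
ratio 0, 80% staggered ⇔ ratio −2 (the "highly staggered" cutoff). Sites
are classed blunt / middle / staggered at 1/3 and 2/3 staggered reads.

Candidate sites are 20-mers within ≤7 substitutions of a guide next to an
NGG (any IUPAC PAM is supported); stacks of ≥3 unique molecules in the ±3
window are tested for enrichment against a non-target control with a
one-sided Poisson upper tail, λ = (control + 1) × library-size ratio, and
Benjamini–Hochberg FDR across candidates. Unique molecules are counted
after UMI deduplication (30-nt window, ≤2 UMI mismatches).

The blunt-rate regressor encodes each protospacer/guide pair as 20
position-wise 4×4 indicator matrices flattened to a 320-long one-hot
vector plus the non-seed and seed mismatch counts (322 variables; a reduced
variant keeps positions 11–20, 161 variables) and fits 1,000 trees of
unlimited depth with dropout-style (DART) boosting under 5-fold
cross-validation.

## Worked example

`examples/01_simulate_and_nominate.py` simulates a 50 kb genome with 20
planted target sites, 100 break molecules per site, PCR duplicates and
background noise, then deduplicates and nominates:

```
planted sites: 20   nominated: 20   planted recovered: 20
chrom  start strand  n_mismatches  total_count           fdr
 chr1  37865      +             3          172  0.000000e+00
 chr1  48004      -             1          163 5.102861e-292
 ...
```

All 20 planted sites (0–4 mismatches) are recovered with no false calls.
`examples/02_scission_profiles.py` then reads out the scission profiles:

```
pooled end-structure distribution:
blunt           0.583
overhang_1nt    0.316
overhang_2nt    0.072
overhang_3nt    0.029
other           0.000
```

meaning 58% of breaks were blunt and most of the rest carried 1-nt 5′
overhangs — matching the generator's configured mixture.
`examples/03_blunt_rate_model.py` trains the regressor on a planted
sequence rule and recovers it (held-out Pearson r ≈ 0.95; the 17/18
combination grid is minimal at 17T|18G and maximal at 17G|18C). The other
examples cover SNV allele deltas, pathogenic-deletion triage and
restriction-enzyme footprints.

A console script exposes the same stages for shell use:

```bash
scissionkit simulate --seed 1 --outdir run/
scissionkit dedup --ends run/ends.tsv --out run/pileup.bed
scissionkit nominate --genome run/genome.fa --guides run/guides.tsv \
    --pileup run/pileup.bed --ntc run/ntc.bed --out run/targets.tsv
scissionkit scission --targets run/targets.tsv --pileup run/pileup.bed \
    --ntc run/ntc.bed --out run/scission.tsv
```

plus `train`, `predict`, `snp-delta`, `reframe` and `t7-design`.

## Layout

- `src/scissionkit/simdata.py` — synthetic genomes, break-end reads, restriction fixtures
- `src/scissionkit/breakio.py` — UMI/barcode extraction, mapq filter, dedup, BED pileups
- `src/scissionkit/nominate.py` — guided candidate search, enrichment testing, analytics
- `src/scissionkit/scission.py` — side assignment, blunt rates, classes, footprints
- `src/scissionkit/scissmodel.py` — feature encoding, model training and interpretation
- `src/scissionkit/varimpact.py` — SNV placements and allele-specific deltas
- `src/scissionkit/reframe.py` — pathogenic-deletion triage and T7 construct design
- `src/scissionkit/cli.py` — thin click CLI over the library
- `docs/methods.md` — modelling assumptions, parameter defaults, limitations
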