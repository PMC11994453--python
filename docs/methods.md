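# Methods

## Coordinate model

All genomic coordinates are 0-based half-open; VCF positions are converted
once, at parse time. Protospacers are numbered 1 (PAM-distal 5′ end) to 20
(PAM-adjacent); the SpCas9 PAM is the NGG immediately 3′ of position 20 on
the non-target strand. A *boundary label* b ∈ {14..20} denotes the break
boundary between protospacer positions b and b+1. For a plus-strand target
with protospacer interval [s, s+20), the PAM-proximal read end of a break
at label b is the record (strand '+', pos0 = s + b) and the PAM-distal end
is (strand '−', pos0 = s + 16); minus-strand targets are the mirror image
(proximal at s + 19 − b on '−', distal at s + 3 on '+'). This makes the
central identities direct arithmetic: label 17 = blunt (stacks abut),
labels 16–14 = 1–3-nt 5′ overhangs (stacks overlap by n), labels 18–20 =
n-base gaps (3′ overhangs, relevant for restriction fixtures). The distal
end always maps at the blunt boundary because end repair fills 5′
overhangs in toward the PAM; this asymmetry is what lets a single-position
shift of the proximal stack encode the cut structure.

## What the simulator emulates — and what it does not

`simdata` generates: random genomes with planted protospacer+PAM instances
(per guide: one exact on-target plus mutated off-target copies, 1..k
substitutions placed with a 2:1 weight on the PAM-distal half, emulating
the greater mismatch tolerance there); per-site break molecules whose end
structures follow a per-site blunt fraction and an overhang-length
distribution; uniform background breaks on both strands; 8-nt UMIs drawn
uniformly from the 4⁸ space, one per ligated end; and PCR duplicates that
re-emit a record with identical position and UMI.

Defaults and their reasoning:

- `depth_per_site = 100` unique molecules — a realistic per-site yield for
  a well-covered site and large enough for stable rate estimates.
- `blunt_fraction_rule`: base 0.6, +0.3 if position 17 is G, −0.35 if
  position 18 is G (clipped to [0.05, 0.95]). Averaged over random
  sequence this gives ≈59% blunt breaks, with strongly blunt 17G sites and
  strongly staggered 18G sites — the known qualitative hierarchy.
- `overhang_length_probs = {1: 0.77, 2: 0.17, 3: 0.06}` — most non-blunt
  Cas9 cuts are 1-nt 5′ overhangs, with 2- and 3-nt tails.
- `mismatch_blunt_penalty = 0.03` per planted mismatch — reproduces the
  weak negative blunt-rate/mismatch trend.
- `noise_rate = 1e-4` ends per bp per strand. The background DSB rate of
  real genomic DNA preps is not a published constant; this value gives a
  few dozen background molecules on a 50-kb toy genome, enough to exercise
  the enrichment statistics without drowning signal.
- `pcr_duplicate_rate = 0.1` — a typical well-behaved library.

Not modelled: sequencing errors, indel-containing alignments, chromatin or
replication/transcription hotspot structure in the background, UMI errors
beyond what the Hamming-2 dedup absorbs, and mappability. Consequently,
passing tests demonstrate the correctness of the *inference machinery*
(coordinate handling, counting, statistics, model recovery), not
robustness to alignment artefacts or biased backgrounds in real data.

A separate helper builds non-target control libraries (background only) at
a chosen total depth, reflecting that controls are sequenced to a depth
comparable with the target library; the enrichment test also accepts an
explicit library-size ratio for unmatched designs.

## Deduplication

Reads are grouped by (sample barcode, chromosome, strand) and scanned in
position order. A record joins an open cluster if it lies within 30 nt of
the cluster anchor and its UMI is within Hamming distance 2 of the anchor
UMI; otherwise it founds a new cluster. One representative per cluster
survives — the first-seen record at its own position. The anchor-based
window (rather than a sliding chain) is a deliberate choice: it is
deterministic, idempotent, and cannot chain arbitrarily long runs of
records into one cluster. N bases mismatch everything, including another
N (conservative). Setting the UMI distance to −1 disables clustering so
only exact (position, UMI) duplicates collapse; this mode is used where
unbiased molecule counts matter more than duplicate removal. UMI-collision
losses at very deep single positions (two distinct molecules within
Hamming 2) are a known small negative bias of the default mode.

## Nomination statistics

Candidates are all 20-mers within ≤7 substitutions of a guide spacer
adjacent to the PAM pattern (IUPAC-aware, default NGG; bulges are out of
scope). The scan is vectorized over sliding windows and is tested to agree
exactly with a brute-force Hamming scan. Molecules are tallied in the
scission window (labels 14–20 proximal, plus the fixed distal position);
stacks of ≥3 molecules are tested for enrichment over the non-target
control with a one-sided Poisson upper tail, λ = (control count + 1) ×
(target library size / control library size). The +1 pseudocount keeps
sites absent from the control testable; BH correction is applied across
the candidates of a run. The smallest admissible stack (3 molecules vs an
empty control at ratio 1) has p = P(Pois(1) ≥ 3) ≈ 0.080 — such minimal
sites therefore clear FDR thresholds of 0.1 but not 0.05; well-covered
sites are unaffected. Targets attributable to two or more pool guides
within Hamming 7 of the locus are removed as ambiguous.

For nuclease-variant panels, Activity is the variant's total on-target
molecule count normalized by the reference nuclease's, and Specificity is
reported both as on/(on+off) (headline; higher = more specific) and as the
raw off/on ratio, since the verbal definition in circulation is ambiguous
between the two.

## Scission profiling

Profiles are computed only for NGG sites (elsewhere the expected cut
position is ill-defined). The fraction-form blunt rate uses raw counts
(no pseudocount); the log2 form adds +1 to numerator and denominator — the
pseudocount is required for the regression response and is applied to all
log2 outputs for consistency. Sites need ≥16 proximal molecules for rate
statistics (≥8 in variant-comparison settings); both thresholds are
parameters. Class bounds at 1/3 and 2/3 staggered reads are left-closed
([0,1/3) blunt, [1/3,2/3) middle, [2/3,1] staggered) — the exact boundary
convention is not externally fixed, so the deterministic, order-preserving
choice was made. The modal-label footprint breaks ties toward the blunt
boundary.

## Blunt-rate model

Encoding: per position, a 4×4 protospacer-base × guide-base indicator
matrix, flattened column-major (guide base outer, A<C<G<T), concatenated
over positions 1–20 (320 variables) plus the non-seed (1–10) and seed
(11–20) mismatch counts — 322 in total. The reduced flavor keeps positions
11–20 and the seed mismatch count (161 variables); it is the flavor used
for allele-delta prediction where only PAM-proximal context matters. Any
consistent cell ordering is model-equivalent; ours is fixed and tested.

Training instances: sites with ≥16 raw proximal molecules; per guide, at
most 100 sites, and the blunt (fraction > 0.8) / staggered (fraction <
0.2) imbalance K is corrected by subsampling the majority class toward
parity. (A one-sided "keep staggered with probability 1/K" rule produces
probabilities above 1 whenever staggered sites are the minority; the
symmetric form is the well-defined generalization.) Selection is
deterministic under a seed.

Regressor: 1,000 trees, unlimited depth (`grow_policy=lossguide`),
dropout-style DART boosting, 5-fold cross-validation; the reported
performance metric is the Pearson correlation between out-of-fold
predictions and observed responses, and the shipped model is refit on all
instances. Numerical choice: with dropout rate 0 — the default, as no
dropout rate is fixed by the protocol — a DART ensemble is mathematically
identical to plain gradient boosting, so the fit is routed through the
cached-prediction gbtree code path, which is dramatically faster than the
uncached DART path (whose training cost grows quadratically with tree
count); `rate_drop > 0` switches to the explicit DART booster. Determinism
is guaranteed by single-threaded training with a fixed seed; models
serialize to JSON plus a metadata sidecar and round-trip to bit-identical
predictions.

Interpretation: per-variable gain importances are scaled to the maximum;
position-level importances sum the four guide-base cells per (position,
protospacer base). Per-position nucleotide effects are one-factor
least-squares fits under a sum-to-zero contrast (each base's coefficient
is its group mean minus the mean of observed group means; unobserved bases
are flagged undefined). The 17/18 combination grid substitutes each of the
16 base pairs into every background sequence and averages predictions.

The planted-rule generator used in validation makes 17G strongly
blunt-promoting (+3), 18G strongly staggered-promoting (−3), with weaker
17T (−0.5) and 18C (+0.5) effects so that the most staggered combination
is 17T|18G and the most blunt 17G|18C — mirroring the observed hierarchy
and making the grid extremes deterministic rather than tie-broken.

## Allele-specific scission (varimpact)

For each biallelic SNV, every placement on either strand where the variant
occupies protospacer position 17 or 18 of an NGG-adjacent 20-mer is
enumerated (the PAM itself is never affected, as both positions are inside
the protospacer; the reference allele must match the genome). Each allele
is scored with a perfectly matched guide and the reported delta is
predicted(ALT) − predicted(REF), antisymmetric by construction. Placement
enumeration is tested against a brute-force scan. Genotype information is
pass-through metadata; the prediction is allele-based.

## Pathogenic-deletion triage (reframe)

Filters: 1-nt deletions only (VCF anchor convention), standard
chromosomes, Pathogenic/Likely_pathogenic significance, deleted base
overlapping a CDS exon; per-filter drop tallies are reported and sum to
input − output. Guides are placed on the *deletion allele*: NGG on either
strand with the deletion junction 0–4 nt from the PAM-proximal protospacer
edge (0 = directly adjacent). The templated +1 insertion duplicates the
protospacer position-17 base at the blunt boundary (between positions 17
and 18) — the fill-in product of a 1-nt 5′ overhang. Frame recovery
compares CDS length mod 3 through the deletion+insertion edit; protein
recovery requires exact equality of the translated CDS with the reference
protein (codon degeneracy is what makes this possible when the inserted
base differs from the deleted one). If the cut boundary falls outside the
CDS, the outcome is DNA-level only and the protein flag is null.
Candidates are classed by predicted log2 blunt rate: blunt (>0), staggered
(<0), highly staggered (≤ −2, i.e. ≥80% staggered cuts — the regime in
which templated insertions dominate); multi-model runs report per-model
and intersection/exclusive counts. T7 constructs are promoter
(GGATCCTAATACGACTCACTATAG) + spacer with its 5′-terminal base forced to G
+ scaffold (GTTTTAGAGCTAGAA), 59 nt. The G substitution targets the
spacer's 5′ (PAM-distal) end; descriptions that number this "position 20"
under a PAM-adjacent-is-20 convention are internally inconsistent, so the
unambiguous 5′-terminal reading is used.

The transcript model used here is deliberately minimal: ordered exon
blocks that are all coding, with the frame starting at the first base.
Splice-junction edits map the inserted base into the downstream exon;
isoform arbitration beyond "first overlapping transcript" is out of scope.

## Validation problem sizes

The shipped verification suite uses desk-scale designs chosen to keep the
whole run fast while leaving comfortable statistical margins: 50–100 kb
genomes with 20 planted sites for nomination (recall and brute-force
agreement), 50 noise-only replicates for the false-call rate, 310 cuts
across overhangs −3..+3 for footprint recovery, 500 depth-100 sites across
planted blunt fractions 0.1–0.9 for estimator coverage (exact binomial
99% intervals), 5,000 rule instances for model recovery, and 500 random
toy CDS cases for the reframe translation oracle.

## Known limitations

- Substitution-only target search; RNA/DNA bulges are not modelled.
- 3′-overhang chemistry for Cas9 is treated only as non-blunt signal
  (labels 18–20), matching the biology of RuvC flexibility being 5′-sided.
- The Poisson enrichment test assumes a locally uniform background; real
  backgrounds (fragile sites, transcription) are overdispersed, so
  genome-wide FDR on real data should be read conservatively.
- The synthetic rule generator is additive; epistatic sequence effects are
  not planted, so model validation certifies recovery of additive signal.
- Real-data headline statistics (genome-wide blunt fractions, database
  site counts, cross-assay model correlation) require the original
  sequencing datasets and external variant databases, which this package
  does not download; all shipped numbers are computed on synthetic data.
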