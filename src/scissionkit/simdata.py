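"""Synthetic genomes and break-end sequencing data with known ground truth.

The simulator emulates the essential chemistry of DSB end-capture sequencing
of in-vitro Cas9-digested genomic DNA: every double-strand break yields two
end-repaired fragments whose terminal aligned bases flank the cut, read
directionality is preserved (the two sides map to opposite strands), each
ligated end carries a random 8-nt UMI, PCR re-samples some molecules, and a
uniform background of spontaneous breaks is added.

End-structure footprint (the core signal the downstream modules decode):

* blunt cut     -> PAM-proximal read at boundary label 17, PAM-distal read
                   abutting it (always at label 17, because the fill-in
                   reaction runs toward the PAM);
* n-nt 5' overhang -> proximal read shifts to label ``17 - n`` and now
                   overlaps the distal read by n bases;
* n-nt 3' overhang (restriction-enzyme fixtures) -> proximal read at label
                   ``17 + n``, leaving an n-base gap.

Coordinates: for a plus-strand target with protospacer interval ``[s, s+20)``
the proximal record is ``(strand '+', pos0 = s + b)`` for boundary label
``b`` and the distal record is ``(strand '-', pos0 = s + 16)``; minus-strand
targets are the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    BASES,
    BLUNT_LABEL,
    PROTOSPACER_LEN,
    random_dna,
    revcomp,
)

END_COLUMNS = ["chrom", "pos0", "strand", "umi", "barcode", "mapq"]
UMI_LEN = 8


def default_blunt_rule() -> dict[tuple[str, str], float]:
    """Blunt-cut probability by (protospacer base 17, base 18).

    Encodes the dominant sequence rule observed for SpCas9: a G at position
    17 strongly favours blunt cuts, a G at position 18 favours staggered
    ones, and the background sits near the genome-wide blunt fraction.
    """
    rule = {}
    for b17 in BASES:
        for b18 in BASES:
            p = 0.6
            if b17 == "G":
                p += 0.3
            if b18 == "G":
                p -= 0.35
            rule[(b17, b18)] = float(np.clip(p, 0.05, 0.95))
    return rule


@dataclass
class SimConfig:
    """Parameters of one simulated experiment (defaults are the study scale).

    ``noise_rate`` is expressed as background read ends per bp per strand;
    ``mismatch_blunt_penalty`` lowers a site's blunt fraction per planted
    mismatch, emulating the observed negative blunt-rate/mismatch trend.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 50_000
    n_guides: int = 5
    offtargets_per_guide: int = 3
    max_planted_mismatches: int = 4
    depth_per_site: int = 100
    blunt_fraction_rule: dict[tuple[str, str], float] = field(default_factory=default_blunt_rule)
    overhang_length_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.77, 2: 0.17, 3: 0.06}
    )
    noise_rate: float = 1e-4
    pcr_duplicate_rate: float = 0.1
    mismatch_blunt_penalty: float = 0.03
    barcode: str = "AACCGGTT"

    def validate(self) -> None:
        if self.chrom_length < 200:
            raise ValueError("chrom_length must be >= 200")
        if not 0 <= self.max_planted_mismatches <= 7:
            raise ValueError("max_planted_mismatches must be in [0, 7]")
        if not 0 <= self.pcr_duplicate_rate < 1:
            raise ValueError("pcr_duplicate_rate must be in [0, 1)")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        for key, p in self.blunt_fraction_rule.items():
            if not 0 <= p <= 1:
                raise ValueError(f"blunt_fraction_rule[{key}] outside [0, 1]")
        if set(self.overhang_length_probs) - {1, 2, 3}:
            raise ValueError("overhang lengths must be within {1, 2, 3}")
        total = sum(self.overhang_length_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("overhang_length_probs must sum to 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated run: planted sites and the guide panel."""

    sites: pd.DataFrame  # chrom, start, end, strand, guide, pam, protospacer, ...
    guides: pd.DataFrame  # name, spacer


# mismatch placement weights: PAM-distal half is more permissive, as seen in
# real off-target compendia
_MM_WEIGHTS = np.array([2.0] * 10 + [1.0] * 10)
_MM_WEIGHTS = _MM_WEIGHTS / _MM_WEIGHTS.sum()


def _true_blunt_fraction(cfg: SimConfig, protospacer: str, n_mm: int) -> float:
    p = cfg.blunt_fraction_rule[(protospacer[16], protospacer[17])]
    p -= cfg.mismatch_blunt_penalty * n_mm
    return float(np.clip(p, 0.02, 0.98))


def gen_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate a random genome with planted protospacer+PAM instances.

    Each guide gets one exact on-target and ``offtargets_per_guide`` mutated
    copies (1..max_planted_mismatches substitutions, never in the PAM GG).
    Planted sites never overlap; placement failure raises a sizing error.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genome = {c: list(random_dna(rng, config.chrom_length)) for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    guides = pd.DataFrame(
        {
            "name": [f"guide{i + 1}" for i in range(config.n_guides)],
            "spacer": [random_dna(rng, PROTOSPACER_LEN) for _ in range(config.n_guides)],
        }
    )

    rows = []
    for _, g in guides.iterrows():
        for k_site in range(1 + config.offtargets_per_guide):
            if k_site == 0 or config.max_planted_mismatches == 0:
                n_mm = 0
            else:
                n_mm = int(rng.integers(1, config.max_planted_mismatches + 1))
            positions = ()
            protospacer = g["spacer"]
            if n_mm:
                positions = tuple(
                    sorted(rng.choice(20, size=n_mm, replace=False, p=_MM_WEIGHTS) + 1)
                )
                proto = list(protospacer)
                for p in positions:
                    old = proto[p - 1]
                    proto[p - 1] = rng.choice([b for b in BASES if b != old])
                protospacer = "".join(proto)
            pam = rng.choice(list(BASES)) + "GG"
            site = _place_site(rng, genome, occupied, protospacer, pam)
            rows.append(
                {
                    "chrom": site[0],
                    "start": site[1],
                    "end": site[1] + PROTOSPACER_LEN,
                    "strand": site[2],
                    "guide": g["name"],
                    "pam": pam,
                    "protospacer": protospacer,
                    "mismatch_positions": ",".join(map(str, positions)),
                    "n_mismatches": n_mm,
                    "true_blunt_fraction": _true_blunt_fraction(config, protospacer, n_mm),
                }
            )

    sites = pd.DataFrame(rows)
    for n, p in sorted(config.overhang_length_probs.items()):
        sites[f"p_overhang{n}"] = p
    return {c: "".join(s) for c, s in genome.items()}, SimTruth(sites=sites, guides=guides)


def _place_site(rng, genome, occupied, protospacer, pam, max_tries=2000):
    """Pick a non-overlapping location and write protospacer+PAM into it."""
    chroms = sorted(genome)
    footprint = PROTOSPACER_LEN + len(pam)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = len(genome[chrom])
        strand = "+" if rng.random() < 0.5 else "-"
        # keep a margin so reads around the cut stay inside the contig
        s = int(rng.integers(40, length - footprint - 40))
        if strand == "+":
            block = (s - 5, s + footprint + 5)
        else:
            block = (s - len(pam) - 5, s + PROTOSPACER_LEN + 5)
        if any(not (block[1] <= a or block[0] >= b) for a, b in occupied[chrom]):
            continue
        seq = genome[chrom]
        if strand == "+":
            seq[s : s + PROTOSPACER_LEN] = protospacer
            seq[s + PROTOSPACER_LEN : s + footprint] = pam
        else:
            seq[s : s + PROTOSPACER_LEN] = revcomp(protospacer)
            seq[s - len(pam) : s] = revcomp(pam)
        occupied[chrom].append(block)
        return chrom, s, strand
    raise ValueError("genome too short to place all sites without overlap")


def _proximal_record(start: int, strand: str, label: int) -> tuple[int, str]:
    if strand == "+":
        return start + label, "+"
    return start + 19 - label, "-"


def _distal_record(start: int, strand: str) -> tuple[int, str]:
    if strand == "+":
        return start + 16, "-"
    return start + 3, "+"


def _umis(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, UMI_LEN))
    return ["".join(BASES[i] for i in row) for row in idx]


def simulate_break_ends(
    truth: SimTruth,
    genome: dict[str, str],
    config: SimConfig,
    overhang_mode: str = "5prime",
) -> pd.DataFrame:
    """Simulate aligned break-end records (with UMIs) for every planted site.

    Each site emits exactly ``depth_per_site`` break molecules; a molecule
    contributes one PAM-proximal and one PAM-distal record, each with its own
    UMI (the two ends are ligated independently). ``overhang_mode`` selects
    5' overhangs (Cas9-like; proximal label ``17 - n``) or 3' overhangs
    (proximal label ``17 + n``). Background noise is uniform on both strands
    and PCR duplicates re-emit records with identical position and UMI.
    """
    config.validate()
    if overhang_mode not in ("5prime", "3prime"):
        raise ValueError("overhang_mode must be '5prime' or '3prime'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB5EA]))
    oh_lengths = np.array(sorted(config.overhang_length_probs), dtype=int)
    oh_probs = np.array([config.overhang_length_probs[n] for n in oh_lengths])

    chrom_col, pos_col, strand_col = [], [], []
    for _, site in truth.sites.iterrows():
        if site["end"] > len(genome[site["chrom"]]):
            raise ValueError(f"site {site['chrom']}:{site['start']} outside genome")
        depth = config.depth_per_site
        blunt = rng.random(depth) < site["true_blunt_fraction"]
        n_stag = int((~blunt).sum())
        overhangs = np.zeros(depth, dtype=int)
        if n_stag:
            overhangs[~blunt] = rng.choice(oh_lengths, size=n_stag, p=oh_probs)
        if overhang_mode == "3prime":
            labels = BLUNT_LABEL + overhangs
        else:
            labels = BLUNT_LABEL - overhangs
        for lab in labels:
            ppos, pstrand = _proximal_record(site["start"], site["strand"], int(lab))
            dpos, dstrand = _distal_record(site["start"], site["strand"])
            chrom_col += [site["chrom"], site["chrom"]]
            pos_col += [ppos, dpos]
            strand_col += [pstrand, dstrand]

    # uniform background on both strands
    for chrom in sorted(genome):
        length = len(genome[chrom])
        n_noise = rng.poisson(config.noise_rate * length * 2)
        if n_noise:
            pos = rng.integers(0, length, size=n_noise)
            strands = rng.choice(["+", "-"], size=n_noise)
            chrom_col += [chrom] * n_noise
            pos_col += list(map(int, pos))
            strand_col += list(strands)

    ends = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos0": pos_col,
            "strand": strand_col,
            "umi": _umis(rng, len(chrom_col)),
            "barcode": config.barcode,
            "mapq": 60,
        }
    )

    if config.pcr_duplicate_rate > 0 and len(ends):
        dup_mask = rng.random(len(ends)) < config.pcr_duplicate_rate
        ends = pd.concat([ends, ends[dup_mask]], ignore_index=True)
    return ends[END_COLUMNS]


def planted_rule_response(protospacer: str) -> float:
    """Synthetic log2 blunt-rate rule for model-recovery experiments.

    Additive sequence rule on the protospacer mirroring the known effect
    hierarchy: G at position 17 strongly promotes blunt cuts (+3), G at 18
    strongly promotes staggered cuts (-3); secondary effects make T at 17
    mildly staggered-promoting (-0.5) and C at 18 mildly blunt-promoting
    (+0.5), so the most staggered combination is 17T|18G and the most blunt
    17G|18C.
    """
    r = 0.0
    b17, b18 = protospacer[16], protospacer[17]
    if b17 == "G":
        r += 3.0
    elif b17 == "T":
        r -= 0.5
    if b18 == "G":
        r -= 3.0
    elif b18 == "C":
        r += 0.5
    return r


def make_rule_instances(n: int, seed: int = 0, noise_sd: float = 0.5) -> pd.DataFrame:
    """Training instances drawn from :func:`planted_rule_response` + noise.

    Guides match their protospacers exactly (the rule is purely a
    protospacer-sequence effect).
    """
    rng = np.random.default_rng(seed)
    protos = [random_dna(rng, PROTOSPACER_LEN) for _ in range(n)]
    y = np.array([planted_rule_response(s) for s in protos])
    y = y + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {"protospacer": protos, "guide_spacer": protos, "log2_blunt_rate": y}
    )


def simulate_nontarget_control(
    genome: dict[str, str],
    config: SimConfig,
    total_molecules: int,
) -> pd.DataFrame:
    """A non-target control library: uniform background only, given depth.

    Emulates a library prepared without the targeting RNP and sequenced to a
    chosen total unique-molecule count (controls are normally sequenced to a
    depth comparable with the target library).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x17C]))
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    per_chrom = rng.multinomial(total_molecules, lengths / lengths.sum())
    chrom_col, pos_col, strand_col = [], [], []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        chrom_col += [chrom] * int(n)
        pos_col += list(map(int, rng.integers(0, len(genome[chrom]), size=int(n))))
        strand_col += list(rng.choice(["+", "-"], size=int(n)))
    ends = pd.DataFrame(
        {
            "chrom": chrom_col, "pos0": pos_col, "strand": strand_col,
            "umi": _umis(rng, len(chrom_col)), "barcode": config.barcode, "mapq": 60,
        }
    )
    if config.pcr_duplicate_rate > 0 and len(ends):
        dup_mask = rng.random(len(ends)) < config.pcr_duplicate_rate
        ends = pd.concat([ends, ends[dup_mask]], ignore_index=True)
    return ends[END_COLUMNS]


def simulate_restriction_fixture(
    cut_site_spec: dict,
    genome: dict[str, str],
    depth: int = 50,
    seed: int = 0,
    barcode: str = "AACCGGTT",
) -> pd.DataFrame:
    """Two read-end stacks whose separation encodes a fixed overhang.

    ``cut_site_spec`` needs ``chrom``, ``position`` (0-based boundary
    coordinate of the top-strand cut) and ``overhang_signed_length``
    (0 = blunt, +n = n-nt 5' overhang -> stacks overlap by n, -n = n-nt 3'
    overhang -> gap of n).
    """
    chrom = cut_site_spec["chrom"]
    c = int(cut_site_spec["position"])
    overhang = int(cut_site_spec["overhang_signed_length"])
    if abs(overhang) > 10:
        raise ValueError("overhang length must satisfy |overhang| <= 10")
    if chrom not in genome or not 0 <= c <= len(genome[chrom]):
        raise ValueError(f"cut site {chrom}:{c} outside genome")
    rng = np.random.default_rng(seed)
    right = pd.DataFrame(
        {"chrom": chrom, "pos0": c - overhang, "strand": "+",
         "umi": _umis(rng, depth), "barcode": barcode, "mapq": 60}
    )
    left = pd.DataFrame(
        {"chrom": chrom, "pos0": c - 1, "strand": "-",
         "umi": _umis(rng, depth), "barcode": barcode, "mapq": 60}
    )
    return pd.concat([right, left], ignore_index=True)[END_COLUMNS]


# ---------------------------------------------------------------------------
# plain-text writers (FASTA / TSV / FASTQ)

def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: SimTruth, sites_path, guides_path=None) -> None:
    truth.sites.to_csv(sites_path, sep="\t", index=False)
    if guides_path is not None:
        truth.guides.to_csv(guides_path, sep="\t", index=False)


def write_ends_tsv(ends: pd.DataFrame, path) -> None:
    ends.to_csv(path, sep="\t", index=False)


def read_ends_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"umi": str, "barcode": str})


def write_fastq(ends: pd.DataFrame, genome: dict[str, str], path, read_len: int = 50) -> None:
    """Emit read-1 FASTQ records: 8-nt UMI + 8-nt barcode + genomic sequence.

    The genomic portion runs from the break end outward (away from the
    break), matching the library orientation the aligner would see.
    """
    with open(path, "w") as fh:
        for i, rec in enumerate(ends.itertuples(index=False)):
            seq = genome[rec.chrom]
            if rec.strand == "+":
                insert = seq[rec.pos0 : rec.pos0 + read_len]
            else:
                lo = max(0, rec.pos0 - read_len + 1)
                insert = revcomp(seq[lo : rec.pos0 + 1])
            read = rec.umi + rec.barcode + insert
            fh.write(f"@read{i} {rec.chrom}:{rec.pos0}:{rec.strand}\n{read}\n+\n{'I' * len(read)}\n")
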