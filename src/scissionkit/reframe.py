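"""Triage of pathogenic 1-nt deletions correctable by templated insertions.

A staggered Cas9 cut with a 1-nt 5' overhang is preferentially repaired by
duplicating the base at protospacer position 17 (+1 templated insertion).
For a pathogenic single-base deletion sitting next to an NGG PAM, a guide
targeting the deletion allele can therefore drive an insertion at the cut
that restores the reading frame — and, when codon degeneracy cooperates,
the exact original protein. This module filters candidate deletions,
enumerates guide placements on the deletion allele, determines the
templated-insertion outcome at DNA and protein level, ranks candidates by
predicted staggeredness, and emits T7 in-vitro-transcription constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seq import PAM_LEN, PROTOSPACER_LEN, check_spacer, revcomp
from .breakio import is_standard_chrom
from .scissmodel import BluntRateModel

T7_PROMOTER = "GGATCCTAATACGACTCACTATAG"
SGRNA_SCAFFOLD = "GTTTTAGAGCTAGAA"
PATHOGENIC_LABELS = {"Pathogenic", "Likely_pathogenic"}
BLUNT_POS = 17  # templated insert = protospacer base at this position


@dataclass
class Transcript:
    """A coding transcript: ordered exon blocks, all of them CDS."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by genome coord

    def validate(self, genome: dict[str, str]) -> None:
        if self.chrom not in genome:
            raise ValueError(f"transcript {self.name}: unknown chromosome {self.chrom}")
        L = len(genome[self.chrom])
        for s, e in self.exons:
            if not 0 <= s < e <= L:
                raise ValueError(f"transcript {self.name}: exon ({s},{e}) outside genome")

    def cds(self, seq: str) -> str:
        spliced = "".join(seq[s:e] for s, e in self.exons)
        return revcomp(spliced) if self.strand == "-" else spliced


def read_transcripts_tsv(path) -> list[Transcript]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for rec in df.itertuples(index=False):
        starts = [int(x) for x in str(rec.exon_starts).split(",") if x]
        ends = [int(x) for x in str(rec.exon_ends).split(",") if x]
        out.append(
            Transcript(
                name=rec.transcript,
                chrom=rec.chrom,
                strand=rec.strand,
                exons=sorted(zip(starts, ends)),
            )
        )
    return out


def load_clinvar_like_vcf(vcf_path) -> pd.DataFrame:
    """Read a VCF with a CLNSIG INFO field into a variant table."""
    from cyvcf2 import VCF

    rows = []
    for var in VCF(str(vcf_path)):
        sig = var.INFO.get("CLNSIG") or ""
        for alt in var.ALT:
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF.upper(),
                    "alt": alt.upper(),
                    "significance": str(sig),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "significance"])


def _deleted_base_pos0(rec) -> int | None:
    """0-based position of the deleted base, or None if not a 1-nt deletion."""
    if len(rec.ref) - len(rec.alt) != 1 or not rec.ref.startswith(rec.alt):
        return None
    return rec.pos - 1 + len(rec.alt)


def find_correctable_deletions(
    variants: pd.DataFrame,
    transcripts: list[Transcript],
    genome: dict[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Filter variants down to pathogenic, exonic 1-nt deletions.

    Returns the surviving records (with the deleted-base coordinate and the
    overlapping transcript names) and a per-filter audit tally whose dropped
    counts sum to input minus output.
    """
    for t in transcripts:
        t.validate(genome)
    audit = {
        "input": len(variants),
        "not_1nt_deletion": 0,
        "nonstandard_chrom": 0,
        "wrong_significance": 0,
        "not_exonic": 0,
    }
    rows = []
    for rec in variants.itertuples(index=False):
        d = _deleted_base_pos0(rec)
        if d is None:
            audit["not_1nt_deletion"] += 1
            continue
        if not is_standard_chrom(rec.chrom):
            audit["nonstandard_chrom"] += 1
            continue
        if rec.significance not in PATHOGENIC_LABELS:
            audit["wrong_significance"] += 1
            continue
        if rec.chrom in genome:
            span = genome[rec.chrom][rec.pos - 1 : rec.pos - 1 + len(rec.ref)]
            if span != rec.ref:
                raise ValueError(
                    f"variant {rec.chrom}:{rec.pos} REF {rec.ref!r} does not match genome {span!r}"
                )
        overlapping = [
            t.name
            for t in transcripts
            if t.chrom == rec.chrom and any(s <= d < e for s, e in t.exons)
        ]
        if not overlapping:
            audit["not_exonic"] += 1
            continue
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "significance": rec.significance,
                "deleted_pos0": d,
                "deleted_base": rec.ref[len(rec.alt)],
                "transcripts": ",".join(overlapping),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "significance",
            "deleted_pos0", "deleted_base", "transcripts",
        ],
    )
    audit["output"] = len(out)
    return out, audit


def _deletion_allele(seq: str, d: int) -> str:
    return seq[:d] + seq[d + 1 :]


def place_guides(
    deletion: pd.Series | dict,
    genome: dict[str, str],
    max_offset: int = 4,
) -> pd.DataFrame:
    """NGG guide placements on the deletion allele near the deletion.

    The deletion junction must lie 0..``max_offset`` nt from the
    PAM-proximal edge of the protospacer, on either strand (0 = the PAM
    directly adjacent to the deleted position). Coordinates in the output
    (``start``) are on the deletion allele. Deletions within 25 bp of a
    contig end are skipped.
    """
    rec = deletion if isinstance(deletion, dict) else deletion.to_dict()
    chrom, d = rec["chrom"], int(rec["deleted_pos0"])
    seq = genome[chrom]
    if d < 25 or d > len(seq) - 26:
        return pd.DataFrame(
            columns=["chrom", "start", "strand", "offset", "protospacer", "pam", "insert_base"]
        )
    allele = _deletion_allele(seq, d)
    j = d  # junction index on the deletion allele (first base after it)
    rows = []
    # plus strand: PAM at [t+20, t+23), PAM-proximal edge boundary at t+20
    for offset in range(max_offset + 1):
        t = j + offset - PROTOSPACER_LEN
        if t < 0 or t + PROTOSPACER_LEN + PAM_LEN > len(allele):
            continue
        pam = allele[t + PROTOSPACER_LEN : t + PROTOSPACER_LEN + PAM_LEN]
        if pam[1:] == "GG":
            proto = allele[t : t + PROTOSPACER_LEN]
            rows.append(
                {
                    "chrom": chrom, "start": t, "strand": "+", "offset": offset,
                    "protospacer": proto, "pam": pam,
                    "insert_base": proto[BLUNT_POS - 1],
                }
            )
    # minus strand: PAM (as CCN on the plus strand) at [t-3, t); edge at t
    for offset in range(max_offset + 1):
        t = j - offset
        if t - PAM_LEN < 0 or t + PROTOSPACER_LEN > len(allele):
            continue
        pam = revcomp(allele[t - PAM_LEN : t])
        if pam[1:] == "GG":
            proto = revcomp(allele[t : t + PROTOSPACER_LEN])
            rows.append(
                {
                    "chrom": chrom, "start": t, "strand": "-", "offset": offset,
                    "protospacer": proto, "pam": pam,
                    "insert_base": proto[BLUNT_POS - 1],
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "strand", "offset", "protospacer", "pam", "insert_base"]
    )


def _map_boundary(c: int, d: int, k: int) -> int:
    """Map a reference boundary coordinate through deletion(d) + insertion(k).

    ``d`` is the deleted base (reference coords), ``k`` the insertion point
    (deletion-allele coords). Boundaries strictly right of the deleted base
    shift left by one; boundaries at or right of the insertion point shift
    right by one.
    """
    c1 = c - 1 if c > d else c
    return c1 + 1 if c1 >= k else c1


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def templated_insertion_outcome(
    placement: pd.Series | dict,
    deletion: pd.Series | dict,
    transcript: Transcript,
    genome: dict[str, str],
) -> dict:
    """Outcome of the +1 templated insertion at the blunt-cut boundary.

    The insert is the deletion-allele protospacer base at position 17,
    placed at the boundary between protospacer positions 17 and 18. Frame
    recovery compares CDS length mod 3 of the edited allele against the
    reference; protein recovery requires the translated edited CDS to equal
    the reference protein exactly. If the cut boundary falls outside the
    CDS the protein flag is null (DNA-level outcome only).
    """
    pl = placement if isinstance(placement, dict) else placement.to_dict()
    de = deletion if isinstance(deletion, dict) else deletion.to_dict()
    chrom, d = de["chrom"], int(de["deleted_pos0"])
    seq = genome[chrom]
    allele = _deletion_allele(seq, d)
    t = int(pl["start"])
    insert_base = pl["insert_base"]

    if pl["strand"] == "+":
        k = t + BLUNT_POS  # allele boundary between protospacer pos 17 and 18
        ins_plus = insert_base
    else:
        k = t + PROTOSPACER_LEN - BLUNT_POS
        ins_plus = revcomp(insert_base)
    edited = allele[:k] + ins_plus + allele[k:]

    ref_cds = transcript.cds(seq)
    edited_exons = [(_map_boundary(s, d, k), _map_boundary(e, d, k)) for s, e in transcript.exons]
    edited_tx = Transcript(transcript.name, transcript.chrom, transcript.strand, edited_exons)
    edited_cds = edited_tx.cds(edited)

    frame_restored = len(edited_cds) % 3 == len(ref_cds) % 3
    # insertion point inside the transcript's CDS? (allele coords vs exons
    # mapped through the deletion only)
    in_cds = False
    for s, e in transcript.exons:
        s1 = s - 1 if s > d else s
        e1 = e - 1 if e > d else e
        # the inserted base lengthens exon [s1, e1) exactly when s1 < k <= e1
        if s1 < k <= e1:
            in_cds = True
    protein_restored: bool | None
    if not in_cds:
        protein_restored = None
    elif not frame_restored:
        protein_restored = False
    else:
        protein_restored = _translate(edited_cds) == _translate(ref_cds)
    return {
        "insert_base": insert_base,
        "frame_restored": frame_restored,
        "protein_restored": protein_restored,
    }


def staggered_class(log2_rate: float, highly_staggered_cutoff: float = -2.0) -> str:
    """blunt (> 0), staggered (< 0), highly_staggered (<= cutoff)."""
    if log2_rate > 0:
        return "blunt"
    if log2_rate <= highly_staggered_cutoff:
        return "highly_staggered"
    return "staggered"


def rank_candidates(
    candidates: pd.DataFrame,
    models: dict[str, BluntRateModel],
    highly_staggered_cutoff: float = -2.0,
) -> tuple[pd.DataFrame, dict]:
    """Score candidates with each nuclease model and report set overlaps.

    Adds per-model predicted log2 blunt rate and scission class columns
    (guide = deletion-allele protospacer, no mismatches), sorts ascending by
    the first model's prediction, and summarizes per-model highly-staggered
    sets with their intersection and exclusive counts.
    """
    out = candidates.copy().reset_index(drop=True)
    sets = {}
    for name, model in models.items():
        preds = model.predict(list(out["protospacer"]), list(out["protospacer"]))
        out[f"rate_{name}"] = preds
        out[f"class_{name}"] = [staggered_class(r, highly_staggered_cutoff) for r in preds]
        sets[name] = set(out.index[out[f"class_{name}"] == "highly_staggered"])
    report = {name: len(s) for name, s in sets.items()}
    if len(sets) >= 2:
        names = list(sets)
        inter = set.intersection(*sets.values())
        report["shared"] = len(inter)
        for name in names:
            others = set.union(*(s for n, s in sets.items() if n != name))
            report[f"{name}_exclusive"] = len(sets[name] - others)
    first = next(iter(models))
    out = out.sort_values(f"rate_{first}").reset_index(drop=True)
    return out, report


def design_t7_construct(spacer: str) -> str:
    """T7 IVT template: promoter + spacer (5' base forced to G) + scaffold.

    The spacer's 5'-terminal (PAM-distal) nucleotide is replaced by G for
    efficient T7 transcription; output length is 24 + 20 + 15 = 59.
    """
    spacer = check_spacer(spacer)
    return T7_PROMOTER + "G" + spacer[1:] + SGRNA_SCAFFOLD
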