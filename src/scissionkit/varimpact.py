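"""Allele-specific scission changes at SNVs in protospacer positions 17/18.

A SNV that falls at protospacer position 17 or 18 of an NGG-adjacent
20-mer can flip the cut configuration between alleles (most strongly, base
substitutions to or from G). For every valid placement the reduced
blunt-rate model predicts the log2 blunt rate of the reference and the
alternative allele — each targeted by a perfectly matched guide — and the
reported delta is ``predicted(ALT) - predicted(REF)``.

VCF coordinates are 1-based; all internal coordinates are 0-based half-open
and the conversion happens in exactly one place (:func:`load_snvs`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._seq import PAM_LEN, PROTOSPACER_LEN, revcomp
from .scissmodel import BluntRateModel

SNP_COLUMNS = [
    "chrom", "variant_pos0", "ref", "alt", "start", "end", "strand",
    "snp_position", "pam", "protospacer_ref", "protospacer_alt",
]


def load_snvs(vcf_path) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF; indels/multiallelics are skipped.

    The single 1-based -> 0-based conversion of the package happens here.
    """
    from cyvcf2 import VCF

    rows, skipped = [], 0
    for var in VCF(str(vcf_path)):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        if var.REF.upper() == var.ALT[0].upper():
            skipped += 1
            continue
        rows.append(
            {
                "chrom": var.CHROM,
                "variant_pos0": var.POS - 1,
                "ref": var.REF.upper(),
                "alt": var.ALT[0].upper(),
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNV or multiallelic record(s)")
    return pd.DataFrame(rows, columns=["chrom", "variant_pos0", "ref", "alt"])


def _placement(genome, chrom, v, ref, alt, strand, snp_pos):
    """Build one candidate placement or return None if no NGG / bad ref."""
    seq = genome[chrom]
    L = len(seq)
    if strand == "+":
        start = v - (snp_pos - 1)
        if start < 0 or start + PROTOSPACER_LEN + PAM_LEN > L:
            return None
        pam = seq[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + PAM_LEN]
        if pam[1:] != "GG":
            return None
        proto_ref = seq[start : start + PROTOSPACER_LEN]
        if proto_ref[snp_pos - 1] != ref:
            return None
        proto_alt = proto_ref[: snp_pos - 1] + alt + proto_ref[snp_pos:]
    else:
        start = v - (PROTOSPACER_LEN - snp_pos)
        if start - PAM_LEN < 0 or start + PROTOSPACER_LEN > L:
            return None
        pam = revcomp(seq[start - PAM_LEN : start])
        if pam[1:] != "GG":
            return None
        proto_ref = revcomp(seq[start : start + PROTOSPACER_LEN])
        if proto_ref[snp_pos - 1] != revcomp(ref):
            return None
        proto_alt = proto_ref[: snp_pos - 1] + revcomp(alt) + proto_ref[snp_pos:]
    return {
        "chrom": chrom,
        "variant_pos0": v,
        "ref": ref,
        "alt": alt,
        "start": start,
        "end": start + PROTOSPACER_LEN,
        "strand": strand,
        "snp_position": snp_pos,
        "pam": pam,
        "protospacer_ref": proto_ref,
        "protospacer_alt": proto_alt,
    }


def enumerate_snp_targets(
    genome: dict[str, str],
    variants: pd.DataFrame,
    positions: tuple[int, ...] = (17, 18),
) -> pd.DataFrame:
    """All placements where a SNV occupies protospacer position 17 or 18.

    Both strands are scanned; a single SNV can yield several placements.
    The PAM itself must be NGG on the reference (the variant never sits in
    the PAM, since positions 17/18 are inside the protospacer).
    """
    for p in positions:
        if not 1 <= p <= PROTOSPACER_LEN:
            raise ValueError(f"protospacer position {p} out of range")
    rows = []
    for var in variants.itertuples(index=False):
        if var.chrom not in genome:
            continue
        for strand in "+-":
            for snp_pos in positions:
                placed = _placement(
                    genome, var.chrom, int(var.variant_pos0), var.ref, var.alt,
                    strand, snp_pos,
                )
                if placed is not None:
                    rows.append(placed)
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def predict_allele_delta(model_reduced: BluntRateModel, sites: pd.DataFrame) -> pd.DataFrame:
    """Predicted blunt-rate change between alleles for each placement.

    Each allele is scored with a guide matching it exactly (0 mismatches);
    ``delta = predicted_rate_alt - predicted_rate_ref``. Output is sorted by
    |delta| descending for candidate picking.
    """
    if model_reduced.flavor != "reduced":
        raise ValueError("allele deltas use the reduced (seed-only) model")
    out = sites.copy().reset_index(drop=True)
    if out.empty:
        for col in ("predicted_rate_ref", "predicted_rate_alt", "delta"):
            out[col] = []
        return out
    bad = out["protospacer_ref"] == out["protospacer_alt"]
    if bad.any():
        raise ValueError("REF and ALT protospacers identical for some sites")
    out["predicted_rate_ref"] = model_reduced.predict(
        list(out["protospacer_ref"]), list(out["protospacer_ref"])
    )
    out["predicted_rate_alt"] = model_reduced.predict(
        list(out["protospacer_alt"]), list(out["protospacer_alt"])
    )
    out["delta"] = out["predicted_rate_alt"] - out["predicted_rate_ref"]
    return out.sort_values("delta", key=np.abs, ascending=False).reset_index(drop=True)
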