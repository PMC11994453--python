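"""Reading, filtering and deduplicating break-end records; BED pileup I/O.

A raw record is one aligned read end: ``(chrom, pos0, strand, umi, barcode,
mapq)`` where ``pos0`` is the 0-based coordinate of the break-proximal
terminal aligned base. After molecule-level deduplication, records are
aggregated into strand-resolved pileups ``(chrom, pos0, strand, count)`` —
the atomic evidence unit for all downstream analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import END_COLUMNS, UMI_LEN

PILEUP_COLUMNS = ["chrom", "pos0", "strand", "count"]

_STANDARD_CHROM = re.compile(r"^(chr)?([0-9]+|[XYM]|MT)$")
_UMI_ALPHABET = set("ACGTN")


def is_standard_chrom(name: str) -> bool:
    return bool(_STANDARD_CHROM.match(name))


@dataclass
class ReadRejection:
    reason: str


def extract_umi_barcode(
    read_seq: str,
    whitelist: set[str] | None = None,
    umi_len: int = UMI_LEN,
    barcode_len: int = UMI_LEN,
):
    """Split off the UMI and sample barcode from the 5' end of read 1.

    Returns ``(umi, barcode, trimmed_read)`` or a :class:`ReadRejection`
    when the read is too short or the barcode is not in the whitelist.
    """
    prefix = umi_len + barcode_len
    if len(read_seq) < prefix:
        return ReadRejection(f"read shorter than {prefix} nt")
    umi = read_seq[:umi_len].upper()
    barcode = read_seq[umi_len:prefix].upper()
    if whitelist is not None and barcode not in whitelist:
        return ReadRejection(f"barcode {barcode} not in whitelist")
    return umi, barcode, read_seq[prefix:]


def process_fastq(path, whitelist: set[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Extract UMI/barcode from every read-1 record of a FASTQ file.

    Returns a table (read name, umi, barcode, trimmed sequence) and a tally
    of rejections by reason.
    """
    from Bio import SeqIO

    rows, tally = [], {}
    for rec in SeqIO.parse(str(path), "fastq"):
        res = extract_umi_barcode(str(rec.seq), whitelist=whitelist)
        if isinstance(res, ReadRejection):
            tally[res.reason] = tally.get(res.reason, 0) + 1
            continue
        umi, barcode, trimmed = res
        rows.append({"name": rec.id, "umi": umi, "barcode": barcode, "seq": trimmed})
    return pd.DataFrame(rows, columns=["name", "umi", "barcode", "seq"]), tally


def filter_mapq(ends: pd.DataFrame, min_mapq: int = 60) -> pd.DataFrame:
    """Keep only records mapped with quality >= ``min_mapq`` (order preserved)."""
    return ends[ends["mapq"] >= min_mapq].reset_index(drop=True)


def _umi_codes(umis: pd.Series) -> np.ndarray:
    """Encode UMIs as byte matrix; N (or any non-ACGT) mismatches everything."""
    bad = umis[~umis.str.fullmatch(f"[ACGTN]{{{UMI_LEN}}}")]
    if len(bad):
        raise ValueError(f"malformed UMI(s): {bad.iloc[0]!r}")
    mat = np.frombuffer("".join(umis).encode(), dtype=np.uint8).reshape(len(umis), UMI_LEN)
    return mat


def dedup_survivors(
    ends: pd.DataFrame,
    window_bp: int = 30,
    max_umi_mismatch: int = 2,
) -> pd.DataFrame:
    """The unique-molecule representatives after PCR-duplicate collapsing.

    Within each (barcode, chrom, strand), records are scanned in position
    order. A record joins an open cluster when it lies within ``window_bp``
    of the cluster anchor *and* its UMI is within Hamming distance
    ``max_umi_mismatch`` of the anchor UMI (N mismatches every base). One
    representative per cluster — the first-seen record, at its own position —
    survives. ``max_umi_mismatch=-1`` disables UMI clustering so that only
    exact (position, UMI) duplicates collapse.
    """
    if ends.empty:
        return ends.copy()
    ends = ends.sort_values(["barcode", "chrom", "strand", "pos0"], kind="mergesort")
    codes = _umi_codes(ends["umi"].astype(str))
    n_mask = codes == ord("N")

    survivors = []
    for _, group in ends.groupby(["barcode", "chrom", "strand"], sort=True):
        idx = group.index.to_numpy()
        pos = group["pos0"].to_numpy()
        order = np.arange(len(group))
        gcodes = codes[ends.index.get_indexer(idx)]
        gn = n_mask[ends.index.get_indexer(idx)]
        active: list[tuple[int, int]] = []  # (anchor row in group, anchor pos)
        for i in order:
            active = [a for a in active if pos[i] - a[1] <= window_bp]
            matched = False
            for a_i, _ in active:
                if max_umi_mismatch < 0:
                    ok = pos[i] == pos[a_i] and not (gcodes[i] != gcodes[a_i]).any()
                else:
                    d = int((gcodes[i] != gcodes[a_i]).sum() + ((gn[i] & gn[a_i]).sum()))
                    ok = d <= max_umi_mismatch
                if ok:
                    matched = True
                    break
            if not matched:
                active.append((int(i), int(pos[i])))
                survivors.append(idx[i])

    return ends.loc[survivors]


def dedup_ends(
    ends: pd.DataFrame,
    window_bp: int = 30,
    max_umi_mismatch: int = 2,
) -> pd.DataFrame:
    """Deduplicate (see :func:`dedup_survivors`) and aggregate into pileups.

    Survivors are counted per (chrom, pos0, strand) into unique-molecule
    pileups.
    """
    kept = dedup_survivors(ends, window_bp=window_bp, max_umi_mismatch=max_umi_mismatch)
    if kept.empty:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    pile = (
        kept.groupby(["chrom", "pos0", "strand"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return pile[PILEUP_COLUMNS]


def write_pileup_bed(pileups: pd.DataFrame, path) -> None:
    """Write pileups as BED6 (score column = unique-molecule count)."""
    with open(path, "w") as fh:
        rows = pileups.sort_values(["chrom", "pos0", "strand"])
        for rec in rows.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.pos0}\t{rec.pos0 + 1}\t.\t{rec.count}\t{rec.strand}\n")


def read_pileup_bed(path, standard_chroms_only: bool = False) -> pd.DataFrame:
    """Read a BED6 pileup file; malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError("fewer than 6 BED fields")
                chrom, start, end, _name, score, strand = fields[:6]
                start, end, score = int(start), int(end), int(score)
                if start < 0 or end != start + 1:
                    raise ValueError("expected single-base interval with start >= 0")
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
                if score < 1:
                    raise ValueError("count must be >= 1")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from None
            if standard_chroms_only and not is_standard_chrom(chrom):
                continue
            rows.append({"chrom": chrom, "pos0": start, "strand": strand, "count": score})
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    dup = df.duplicated(subset=["chrom", "pos0", "strand"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (chrom, pos, strand) pileup records")
    return df


def pileup_index(pileups: pd.DataFrame) -> dict[tuple[str, int, str], int]:
    """O(1) lookup table {(chrom, pos0, strand): count}."""
    return {
        (r.chrom, int(r.pos0), r.strand): int(r.count)
        for r in pileups.itertuples(index=False)
    }


__all__ = [
    "END_COLUMNS",
    "PILEUP_COLUMNS",
    "ReadRejection",
    "dedup_ends",
    "dedup_survivors",
    "extract_umi_barcode",
    "filter_mapq",
    "is_standard_chrom",
    "pileup_index",
    "process_fastq",
    "read_pileup_bed",
    "write_pileup_bed",
]
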