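"""Guided nomination of on-/off-target cleavage sites from break-end pileups.

For each guide, every 20-mer adjacent to a PAM on either strand and within a
Hamming distance cap of the spacer is a candidate protospacer. Candidates
are scored by tallying unique break molecules in the scission window
(boundary labels 14..20, i.e. +/-3 nt around the canonical blunt cut) on
the PAM-proximal and PAM-distal sides, and tested for enrichment against a
non-target control library with a one-sided Poisson upper-tail test and
Benjamini-Hochberg FDR control across candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import (
    BLUNT_LABEL,
    IUPAC,
    PAM_LEN,
    PROTOSPACER_LEN,
    SCISSION_LABELS,
    check_spacer,
    encode,
    hamming,
    revcomp,
)
from .breakio import is_standard_chrom, pileup_index

CANDIDATE_COLUMNS = [
    "chrom", "start", "end", "strand", "pam", "protospacer", "guide",
    "n_mismatches", "mismatch_positions", "mm_nonseed", "mm_seed",
]


def _pam_mask(enc: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean mask over windows of len(pattern) matching the IUPAC pattern."""
    win = sliding_window_view(enc, len(pattern))
    mask = np.ones(len(win), dtype=bool)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, p in enumerate(pattern.upper()):
        allowed = [base_idx[b] for b in IUPAC[p]]
        mask &= np.isin(win[:, j], allowed)
    return mask


def _scan_strand(seq: str, spacer_enc: np.ndarray, max_mm: int, pam: str):
    """Yield (start_on_this_strand, n_mm) for every PAM-adjacent 20-mer."""
    enc = encode(seq)
    if len(enc) < PROTOSPACER_LEN + len(pam):
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = sliding_window_view(enc, PROTOSPACER_LEN)
    # non-ACGT genome characters encode as 255 and mismatch every spacer base
    mm = (windows != spacer_enc).sum(axis=1)
    pam_ok = _pam_mask(enc, pam)
    starts = np.arange(len(windows) - len(pam), dtype=int)
    keep = (mm[: len(starts)] <= max_mm) & pam_ok[PROTOSPACER_LEN : PROTOSPACER_LEN + len(starts)]
    return starts[keep], mm[: len(starts)][keep]


def find_candidate_sites(
    genome: dict[str, str],
    guide,
    max_mismatches: int = 7,
    pam_pattern: str = "NGG",
    standard_chroms_only: bool = True,
) -> pd.DataFrame:
    """All protospacer candidates for one guide (statistics unset).

    ``guide`` is ``(name, spacer)`` or a mapping with those keys. Matches are
    substitution-only (no bulges); coordinates are 0-based half-open and the
    reported protospacer sequence is in PAM-adjacent orientation.
    """
    if isinstance(guide, dict):
        name, spacer = guide["name"], guide["spacer"]
    else:
        name, spacer = guide
    spacer = check_spacer(spacer)
    spacer_enc = encode(spacer)

    rows = []
    for chrom in sorted(genome):
        if standard_chroms_only and not is_standard_chrom(chrom):
            continue
        seq = genome[chrom].upper()
        L = len(seq)
        for strand in "+-":
            scan_seq = seq if strand == "+" else revcomp(seq)
            starts, mms = _scan_strand(scan_seq, spacer_enc, max_mismatches, pam_pattern)
            for s, _ in zip(starts, mms):
                proto = scan_seq[s : s + PROTOSPACER_LEN]
                pam = scan_seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + PAM_LEN]
                if strand == "+":
                    start = int(s)
                else:
                    start = L - int(s) - PROTOSPACER_LEN
                positions = tuple(
                    i + 1 for i in range(PROTOSPACER_LEN) if proto[i] != spacer[i]
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + PROTOSPACER_LEN,
                        "strand": strand,
                        "pam": pam,
                        "protospacer": proto,
                        "guide": name,
                        "n_mismatches": len(positions),
                        "mismatch_positions": ",".join(map(str, positions)),
                        "mm_nonseed": sum(1 for p in positions if p <= 10),
                        "mm_seed": sum(1 for p in positions if p > 10),
                    }
                )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def enrichment_pvalue(obs_count: int, ntc_count: int, size_ratio: float) -> float:
    """Upper-tail Poisson probability P(X >= obs) with rate (ntc+1)*size_ratio.

    The +1 pseudocount on the control keeps the rate strictly positive so
    that sites absent from the non-target library remain testable.
    """
    if obs_count < 0 or ntc_count < 0:
        raise ValueError("counts must be >= 0")
    if size_ratio <= 0:
        raise ValueError("size_ratio must be > 0")
    if obs_count == 0:
        return 1.0
    lam = (ntc_count + 1) * size_ratio
    return float(stats.poisson.sf(obs_count - 1, lam))


def _window_positions(start: int, strand: str):
    """Pileup coordinates of the scission window for one candidate.

    Returns (proximal {label: (pos, strand)}, distal (pos, strand)).
    The PAM-distal end maps at the blunt boundary regardless of where the
    non-target strand was cut, because end repair fills in toward the PAM.
    """
    proximal = {}
    for b in SCISSION_LABELS:
        if strand == "+":
            proximal[b] = (start + b, "+")
        else:
            proximal[b] = (start + 19 - b, "-")
    distal = (start + 16, "-") if strand == "+" else (start + 3, "+")
    return proximal, distal


def tally_candidate_counts(candidates: pd.DataFrame, pileup: pd.DataFrame) -> pd.DataFrame:
    """Attach per-boundary-label proximal counts and the distal count."""
    idx = pileup_index(pileup)
    out = candidates.copy()
    prox_cols = {b: [] for b in SCISSION_LABELS}
    distal_col, total_col = [], []
    for rec in candidates.itertuples(index=False):
        proximal, distal = _window_positions(rec.start, rec.strand)
        total = 0
        for b, (pos, st) in proximal.items():
            c = idx.get((rec.chrom, pos, st), 0)
            prox_cols[b].append(c)
            total += c
        d = idx.get((rec.chrom, distal[0], distal[1]), 0)
        distal_col.append(d)
        total_col.append(total + d)
    for b in SCISSION_LABELS:
        out[f"c{b}"] = prox_cols[b]
    out["distal_count"] = distal_col
    out["total_count"] = total_col
    return out


def call_targets(
    candidates: pd.DataFrame,
    pileup: pd.DataFrame,
    ntc_pileup: pd.DataFrame,
    min_stack: int = 3,
    fdr_threshold: float = 0.05,
    size_ratio: float | None = None,
) -> pd.DataFrame:
    """Nominate targets: stack filter, Poisson enrichment vs control, BH FDR.

    A candidate must accumulate at least ``min_stack`` unique molecules in
    the scission window (both sides combined). Library-size scaling defaults
    to the ratio of total molecule counts of the two pileups (pass
    ``size_ratio`` explicitly when the control was sequenced to a very
    different depth than the background of the target library).
    """
    if candidates.empty:
        return candidates.assign(pvalue=[], fdr=[])
    candidates = candidates.reset_index(drop=True)
    if len(pileup) and not set(candidates["chrom"]) & set(pileup["chrom"]):
        raise ValueError("candidate and pileup chromosome names do not overlap")
    tallied = tally_candidate_counts(candidates, pileup)
    ntc_tallied = tally_candidate_counts(candidates, ntc_pileup)
    ntc_total_window = ntc_tallied["total_count"].to_numpy()

    if size_ratio is None:
        target_size = int(pileup["count"].sum()) if len(pileup) else 0
        ntc_size = int(ntc_pileup["count"].sum()) if len(ntc_pileup) else 0
        size_ratio = target_size / ntc_size if ntc_size > 0 else 1.0

    stacked = tallied[tallied["total_count"] >= min_stack].copy()
    if stacked.empty:
        return stacked.assign(pvalue=[], fdr=[])
    pvals = [
        enrichment_pvalue(int(obs), int(ntc), size_ratio)
        for obs, ntc in zip(
            stacked["total_count"], ntc_total_window[stacked.index.to_numpy()]
        )
    ]
    stacked["pvalue"] = pvals
    stacked["fdr"] = multipletests(pvals, method="fdr_bh")[1]
    out = stacked[stacked["fdr"] <= fdr_threshold].reset_index(drop=True)
    return out


def remove_ambiguous(
    guides: pd.DataFrame, targets: pd.DataFrame, max_hamming: int = 7
) -> pd.DataFrame:
    """Drop loci attributable to two or more guides in the pool.

    A target is ambiguous when at least two pool spacers lie within
    ``max_hamming`` substitutions of its protospacer.
    """
    if targets.empty or len(guides) < 2:
        return targets.reset_index(drop=True)
    spacers = list(guides["spacer"])
    keep = []
    for rec in targets.itertuples(index=False):
        n_close = sum(1 for sp in spacers if hamming(rec.protospacer, sp) <= max_hamming)
        keep.append(n_close < 2)
    return targets[np.array(keep)].reset_index(drop=True)


def mismatch_position_profile(targets: pd.DataFrame) -> pd.DataFrame:
    """Fraction of targets mismatched at each protospacer position 1..20."""
    if targets.empty:
        raise ValueError("mismatch profile requires at least one target")
    counts = np.zeros(PROTOSPACER_LEN)
    for mp in targets["mismatch_positions"]:
        if isinstance(mp, str) and mp:
            for p in mp.split(","):
                counts[int(p) - 1] += 1
        elif isinstance(mp, (tuple, list)):
            for p in mp:
                counts[int(p) - 1] += 1
    return pd.DataFrame(
        {"position": np.arange(1, PROTOSPACER_LEN + 1), "mismatch_rate": counts / len(targets)}
    )


def pam_usage(targets: pd.DataFrame) -> pd.DataFrame:
    """PAM trinucleotide frequencies (run nominated with pam_pattern='NNN').

    Also reports N-prefixed class aggregates (NGG / NAG / NGA / other).
    """
    if targets.empty:
        return pd.DataFrame(columns=["pam", "frequency", "pam_class"])
    freq = targets["pam"].value_counts(normalize=True)

    def pam_class(p):
        tail = p[1:]
        return {"GG": "NGG", "AG": "NAG", "GA": "NGA"}.get(tail, "other")

    out = freq.rename("frequency").reset_index().rename(columns={"index": "pam"})
    out["pam_class"] = out["pam"].map(pam_class)
    return out


def pam_class_usage(targets: pd.DataFrame) -> pd.Series:
    table = pam_usage(targets)
    if table.empty:
        return pd.Series(dtype=float)
    return table.groupby("pam_class")["frequency"].sum()


def shannon_complexity(protospacer_seq: str) -> float:
    """Shannon entropy (bits) of the mononucleotide composition of a 20-mer."""
    seq = check_spacer(protospacer_seq)
    freqs = np.array([seq.count(b) for b in "ACGT"], dtype=float) / len(seq)
    nz = freqs[freqs > 0]
    return float(-(nz * np.log2(nz)).sum())


def activity_specificity(
    variant_runs: dict[str, pd.DataFrame], reference_run: pd.DataFrame
) -> pd.DataFrame:
    """Per-nuclease Activity and Specificity scores over matched guide panels.

    Activity = total on-target molecules of the variant / total on-target
    molecules of the reference. Specificity is reported in both circulating
    forms: ``on/(on+off)`` (higher = more specific; headline score) and the
    raw ``off/on`` ratio.
    """
    def on_off(run: pd.DataFrame) -> tuple[int, int]:
        on = int(run.loc[run["n_mismatches"] == 0, "total_count"].sum())
        off = int(run.loc[run["n_mismatches"] > 0, "total_count"].sum())
        return on, off

    ref_on, _ = on_off(reference_run)
    if ref_on == 0:
        raise ValueError("reference run has zero on-target molecules")
    rows = []
    for name, run in variant_runs.items():
        on, off = on_off(run)
        rows.append(
            {
                "nuclease": name,
                "activity": on / ref_on,
                "specificity": on / (on + off) if on + off else np.nan,
                "off_on_ratio": off / on if on else np.inf,
            }
        )
    return pd.DataFrame(rows)
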