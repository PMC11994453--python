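"""Scission profiling: blunt-rate estimation and end-structure inference.

For a nominated target the PAM-proximal break signal is binned by boundary
label (14..20; label 17 = canonical blunt cut). Two blunt-rate forms are
computed:

* ``blunt_fraction`` = c17 / sum(c14..c20), the raw fraction;
* ``log2_blunt_rate`` = log2((c17 + 1) / (sum of the other labels + 1)),
  the pseudocounted log2 ratio used as the regression response.

Without pseudocounts the two are linked by ``ratio = log2(f / (1 - f))``,
so a 50% blunt fraction maps to ratio 0 and an 80% staggered fraction to
ratio -2 — the thresholds used for the blunt / staggered / highly staggered
calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import BLUNT_LABEL, SCISSION_LABELS
from .nominate import enrichment_pvalue, tally_candidate_counts

PROX_COLS = [f"c{b}" for b in SCISSION_LABELS]
OUTSIDE_COLS = [f"c{b}" for b in SCISSION_LABELS if b != BLUNT_LABEL]


def assign_side(record, target) -> tuple[str, int | None]:
    """Classify one pileup record relative to a target.

    Returns ``(side, boundary_label)`` with side in {proximal, distal,
    outside}. Records on the PAM-containing side pointing away from the
    break are proximal with label ``pos0 - start`` (plus-strand targets;
    minus-strand mirrored). The distal geometry is fixed: end repair fills
    in toward the PAM, so distal ends always map at the blunt boundary.
    """
    chrom = record["chrom"] if isinstance(record, dict) else record.chrom
    pos0 = int(record["pos0"] if isinstance(record, dict) else record.pos0)
    rstrand = record["strand"] if isinstance(record, dict) else record.strand
    tchrom = target["chrom"] if isinstance(target, dict) else target.chrom
    start = int(target["start"] if isinstance(target, dict) else target.start)
    tstrand = target["strand"] if isinstance(target, dict) else target.strand
    if chrom != tchrom:
        return "outside", None

    if tstrand == "+":
        if rstrand == "+":
            label = pos0 - start
            return ("proximal", label) if label in SCISSION_LABELS else ("outside", None)
        if pos0 == start + 16:
            return "distal", BLUNT_LABEL
        return "outside", None
    else:
        if rstrand == "-":
            label = start + 19 - pos0
            return ("proximal", label) if label in SCISSION_LABELS else ("outside", None)
        if pos0 == start + 3:
            return "distal", BLUNT_LABEL
        return "outside", None


def blunt_fraction(proximal_counts: dict[int, int]) -> float:
    total = sum(proximal_counts.get(b, 0) for b in SCISSION_LABELS)
    if total == 0:
        return np.nan
    return proximal_counts.get(BLUNT_LABEL, 0) / total


def log2_blunt_rate(proximal_counts: dict[int, int]) -> float:
    """Pseudocounted log2 ratio of blunt signal to non-blunt window signal."""
    c17 = proximal_counts.get(BLUNT_LABEL, 0)
    outside = sum(proximal_counts.get(b, 0) for b in SCISSION_LABELS if b != BLUNT_LABEL)
    return float(np.log2((c17 + 1) / (outside + 1)))


def profile_targets(
    targets: pd.DataFrame,
    pileup: pd.DataFrame,
    min_proximal: int = 16,
    require_ngg: bool = True,
) -> pd.DataFrame:
    """Scission profile for every target (one row per site).

    Adds per-label proximal counts (if not already tallied), both blunt-rate
    forms, the blunt/middle/staggered class, and eligibility flags:
    ``computable`` (any proximal signal) and ``eligible`` (at least
    ``min_proximal`` proximal molecules — rate statistics should only be
    read off eligible sites). With ``require_ngg`` sites whose PAM is not
    NGG are dropped, since only there is the expected cut site well defined.
    """
    out = targets.copy().reset_index(drop=True)
    if require_ngg:
        out = out[out["pam"].str[1:] == "GG"].reset_index(drop=True)
    if not all(c in out.columns for c in PROX_COLS):
        out = tally_candidate_counts(out, pileup)
    prox = out[PROX_COLS].to_numpy()
    prox_total = prox.sum(axis=1)
    c17 = out[f"c{BLUNT_LABEL}"].to_numpy()
    outside = prox_total - c17

    out["proximal_total"] = prox_total
    out["computable"] = prox_total > 0
    out["eligible"] = prox_total >= min_proximal
    with np.errstate(invalid="ignore", divide="ignore"):
        out["blunt_fraction"] = np.where(prox_total > 0, c17 / np.maximum(prox_total, 1), np.nan)
    out["log2_blunt_rate"] = np.log2((c17 + 1) / (outside + 1))
    out["scission_class"] = [
        classify_fraction(f) if t > 0 else None
        for f, t in zip(out["blunt_fraction"], prox_total)
    ]
    return out


def classify_fraction(blunt_frac: float) -> str:
    """Blunt / middle / staggered call from the staggered read fraction.

    Left-closed intervals: staggered fraction in [0, 1/3) -> blunt,
    [1/3, 2/3) -> middle, [2/3, 1] -> staggered.
    """
    if np.isnan(blunt_frac):
        raise ValueError("cannot classify an uncomputable profile")
    staggered = 1.0 - blunt_frac
    if staggered < 1 / 3:
        return "blunt"
    if staggered < 2 / 3:
        return "middle"
    return "staggered"


def classify_site(profile_row) -> str:
    f = profile_row["blunt_fraction"] if isinstance(profile_row, (dict, pd.Series)) else profile_row.blunt_fraction
    return classify_fraction(float(f))


def overhang_distribution(profiles: pd.DataFrame) -> pd.Series:
    """Aggregate end-structure fractions over sites.

    Pools proximal counts across all computable sites: label 17 -> blunt,
    labels 16..14 -> 1..3-nt 5' overhangs, labels 18..20 -> 'other'.
    """
    comp = profiles[profiles.get("computable", pd.Series(True, index=profiles.index))]
    if comp.empty:
        raise ValueError("no computable profiles")
    totals = comp[PROX_COLS].sum()
    grand = totals.sum()
    frac = {
        "blunt": totals[f"c{BLUNT_LABEL}"] / grand,
        "overhang_1nt": totals["c16"] / grand,
        "overhang_2nt": totals["c15"] / grand,
        "overhang_3nt": totals["c14"] / grand,
        "other": (totals["c18"] + totals["c19"] + totals["c20"]) / grand,
    }
    return pd.Series(frac)


def infer_footprint(proximal_label: int, distal_label: int = BLUNT_LABEL, target=None) -> int:
    """Signed overhang length from the stack geometry.

    ``17 - proximal_label``: 0 = blunt, +n = n-nt 5' overhang (stacks
    overlap by n), -n = n-nt 3' overhang (gap of n). The distal stack sits
    at the blunt boundary by construction.
    """
    return BLUNT_LABEL - int(proximal_label)


def footprint_from_stacks(proximal_pos0: int, distal_pos0: int) -> int:
    """Signed overhang from raw stack coordinates (restriction-enzyme mode).

    The distal stack's terminal base sits immediately left of the cut
    boundary, so ``distal_pos0 + 1 - proximal_pos0`` is 0 for abutting
    stacks, +n for an n-base overlap (5' overhang) and -n for an n-base gap
    (3' overhang).
    """
    return int(distal_pos0) + 1 - int(proximal_pos0)


def dominant_footprint(profile_row) -> int:
    """Footprint from the modal proximal boundary label of one site."""
    counts = {b: int(profile_row[f"c{b}"]) for b in SCISSION_LABELS}
    if sum(counts.values()) == 0:
        raise ValueError("no proximal signal")
    modal = max(SCISSION_LABELS, key=lambda b: (counts[b], -abs(b - BLUNT_LABEL)))
    return infer_footprint(modal)


def outside_signal_test(
    profiles: pd.DataFrame, ntc_pileup: pd.DataFrame, size_ratio: float | None = None
) -> pd.DataFrame:
    """Significance of non-blunt signal vs the non-target control.

    Applies the Poisson upper-tail enrichment test to the summed counts at
    labels {14..16, 18..20} against control counts in the same window, with
    BH correction across tested sites.
    """
    out = profiles.copy().reset_index(drop=True)
    ntc = tally_candidate_counts(out[["chrom", "start", "end", "strand"]].assign(
        pam=out["pam"], protospacer=out["protospacer"], guide=out.get("guide", ""),
    ), ntc_pileup)
    ntc_outside = ntc[OUTSIDE_COLS].sum(axis=1).to_numpy()
    obs_outside = out[OUTSIDE_COLS].sum(axis=1).to_numpy()

    if size_ratio is None:
        distal_total = int(out["distal_count"].sum()) if "distal_count" in out.columns else 0
        target_size = int(out["proximal_total"].sum()) + distal_total
        ntc_size = int(ntc_pileup["count"].sum()) if len(ntc_pileup) else 0
        size_ratio = target_size / ntc_size if ntc_size > 0 else 1.0

    pvals = [
        enrichment_pvalue(int(o), int(c), size_ratio)
        for o, c in zip(obs_outside, ntc_outside)
    ]
    out["outside_pvalue"] = pvals
    out["outside_fdr"] = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
    return out


def bluntrate_vs_mismatch(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Blunt rate stratified by mismatch count, with an OLS trend.

    Uses eligible sites only. Returns the per-stratum summary and a dict
    with the least-squares slope and the Pearson correlation of
    blunt_fraction on mismatch count (flagged undefined with one stratum).
    """
    elig = profiles[profiles["eligible"] & profiles["computable"]]
    if elig.empty:
        raise ValueError("no eligible sites")
    table = (
        elig.groupby("n_mismatches")["blunt_fraction"]
        .agg(["count", "mean", lambda s: s.quantile(0.25), "median", lambda s: s.quantile(0.75)])
        .rename(columns={"<lambda_0>": "q25", "<lambda_1>": "q75"})
        .reset_index()
    )
    if elig["n_mismatches"].nunique() < 2:
        return table, {"slope": np.nan, "pearson_r": np.nan, "defined": False}
    res = stats.linregress(elig["n_mismatches"], elig["blunt_fraction"])
    return table, {
        "slope": float(res.slope),
        "pearson_r": float(res.rvalue),
        "pvalue": float(res.pvalue),
        "defined": True,
    }
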