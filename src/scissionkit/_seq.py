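"""Low-level sequence helpers shared across modules.

Conventions used throughout the package:

* Genomic coordinates are 0-based, half-open.
* Protospacers are numbered 1 (PAM-distal 5' end) to 20 (PAM-adjacent);
  the SpCas9 PAM sits immediately 3' of position 20 on the non-target strand.
* A break *boundary label* ``b`` (14..20) names the boundary between
  protospacer positions ``b`` and ``b+1``; label 17 is the canonical blunt
  cut 3 nt upstream of the PAM, labels 16..14 correspond to 1..3-nt
  5' overhangs.
"""

from __future__ import annotations

import numpy as np

PROTOSPACER_LEN = 20
PAM_LEN = 3
BLUNT_LABEL = 17
SCISSION_LABELS = tuple(range(14, 21))  # boundary labels in the [-3, +3] window

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3; other=255)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def hamming(a: str, b: str, n_as_mismatch: bool = True) -> int:
    """Hamming distance between equal-length strings.

    With ``n_as_mismatch`` any position where either string carries a
    non-ACGT character (for example ``N``) counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    ea, eb = encode(a), encode(b)
    diff = ea != eb
    if not n_as_mismatch:
        valid = (ea != 255) & (eb != 255)
        diff &= valid
    else:
        diff |= (ea == 255) | (eb == 255)
    return int(diff.sum())


def pam_matches(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches an IUPAC PAM ``pattern`` of the same length."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC.get(p.upper(), "") for s, p in zip(seq.upper(), pattern))


def check_spacer(spacer: str) -> str:
    """Validate a 20-nt ACGT spacer and return it uppercased."""
    spacer = str(spacer).upper()
    if len(spacer) != PROTOSPACER_LEN:
        raise ValueError(f"spacer must be {PROTOSPACER_LEN} nt, got {len(spacer)}")
    if any(c not in _BASE_INDEX for c in spacer):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    return spacer


def mismatch_positions(protospacer: str, spacer: str) -> tuple[int, ...]:
    """1-based protospacer positions at which the two 20-mers differ."""
    protospacer = check_spacer(protospacer)
    spacer = check_spacer(spacer)
    return tuple(i + 1 for i, (p, s) in enumerate(zip(protospacer, spacer)) if p != s)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
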