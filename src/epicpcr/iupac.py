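"""IUPAC nucleotide codes as 4-bit masks, for degenerate-primer matching.

Each code is a bitmask over {A, C, G, T}; two codes are compatible when
their masks intersect. Encoding sequences as ``numpy.uint8`` mask arrays
lets primer scans and window comparisons run as vectorized bitwise ops.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

A, C, G, T = 1, 2, 4, 8

IUPAC_MASKS: dict[str, int] = {
    "A": A,
    "C": C,
    "G": G,
    "T": T,
    "U": T,
    "R": A | G,
    "Y": C | T,
    "S": C | G,
    "W": A | T,
    "K": G | T,
    "M": A | C,
    "B": C | G | T,
    "D": A | G | T,
    "H": A | C | T,
    "V": A | C | G,
    "N": A | C | G | T,
}

#: number of concrete bases each code stands for
DEGENERACY: dict[str, int] = {c: bin(m).count("1") for c, m in IUPAC_MASKS.items()}

_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASKS.items():
    _MASK_LUT[ord(_code)] = _mask
    _MASK_LUT[ord(_code.lower())] = _mask


def validate_iupac(seq: str, name: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise ``ValueError`` on non-IUPAC chars."""
    s = seq.upper()
    bad = set(s) - set(IUPAC_MASKS)
    if not s:
        raise ValueError(f"{name} must be non-empty")
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an array of 4-bit IUPAC masks."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if (masks == 0).any():
        raise ValueError(f"non-IUPAC character in sequence {seq!r}")
    return masks


def expansion(code: str) -> set[str]:
    """Concrete bases a single IUPAC code stands for, e.g. S -> {C, G}."""
    mask = IUPAC_MASKS.get(code.upper())
    if mask is None:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return {b for b, m in (("A", A), ("C", C), ("G", G), ("T", T)) if mask & m}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
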