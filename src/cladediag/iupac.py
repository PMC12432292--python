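"""IUPAC nucleotide codes as 4-bit masks.

Every residue is a subset of {A, C, G, T}; the mask encodes membership with
one bit per base (A=1, C=2, G=4, T=8). Unions of residue sets and subset
tests — the two operations the motif screen lives on — become bitwise OR
and ``x & ~y == 0``. The gap character maps to mask 0, which is a member of
no set; that single convention implements the "a gap never matches" rule.

Code tables come from :mod:`Bio.Data.IUPACData` rather than being retyped.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import IUPACData

GAP = "-"

#: code -> frozenset of bases, e.g. "Y" -> {"C", "T"}
CODE_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code != "X"  # Biopython lists X as a legacy alias of N
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: code -> 4-bit mask (gap -> 0)
CODE_TO_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in CODE_TO_BASES.items()
}
CODE_TO_MASK[GAP] = 0

#: mask -> minimal IUPAC code covering exactly that base set
MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items()}

ALPHABET = frozenset(CODE_TO_MASK)

#: lookup table indexed by ord(char); 255 marks an illegal character
MASK_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    MASK_LUT[ord(_c)] = _m

DEGENERATE_CODES = frozenset(c for c, b in CODE_TO_BASES.items() if len(b) > 1)


def mask_of(residue: str) -> int:
    """Return the 4-bit mask of a single residue character."""
    return CODE_TO_MASK[residue]


def code_of(mask: int) -> str:
    """Return the minimal IUPAC code for a non-empty base-set mask."""
    if mask == 0:
        raise ValueError("mask 0 (gap/empty set) has no IUPAC code")
    return MASK_TO_CODE[mask]


def is_degenerate(code: str) -> bool:
    return code in DEGENERATE_CODES


def masks_from_string(residues: str) -> np.ndarray:
    """Vectorised residue->mask conversion; assumes residues are normalised."""
    arr = MASK_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    return arr


def string_from_masks(masks: np.ndarray) -> str:
    return "".join(MASK_TO_CODE[int(m)] for m in masks)
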