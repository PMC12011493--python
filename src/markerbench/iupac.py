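"""IUPAC nucleotide ambiguity codes and compatibility semantics.

Every symbol expands to a set of concrete bases; two symbols are *compatible*
when their expansion sets intersect. A gap is compatible with a gap and
incompatible with any base. This strict set-intersection reading is what makes
"distinguishing position" a decidable, testable predicate.
"""

from __future__ import annotations

GAP = "-"

#: Expansion sets for the 15 IUPAC nucleotide symbols.
EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(EXPANSION)

#: Code for each non-empty subset of {A,C,G,T}, inverse of EXPANSION.
CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in EXPANSION.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def compatible(a: str, b: str) -> bool:
    """True if the two symbols can denote the same base.

    Gap/gap is compatible; gap/base is not.
    """
    if a == GAP or b == GAP:
        return a == b
    return bool(EXPANSION[a] & EXPANSION[b])


def is_iupac(symbol: str) -> bool:
    return symbol in IUPAC_ALPHABET


def ambiguous_indices(seq: str) -> set[int]:
    """0-based indices whose symbol is not a concrete A/C/G/T."""
    return {i for i, s in enumerate(seq) if s not in "ACGT"}


#: 4-bit base masks: two symbols are compatible iff their masks intersect.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
MASK: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in EXPANSION.items()
}
MASK[GAP] = 0


def mask_array(seq: str):
    """Sequence as a numpy uint8 array of IUPAC bitmasks (vectorised compare)."""
    import numpy as np

    table = np.zeros(256, dtype=np.uint8)
    for sym, m in MASK.items():
        table[ord(sym)] = m
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
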