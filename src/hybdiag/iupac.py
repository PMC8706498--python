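"""IUPAC nucleotide alphabet helpers.

All sequence comparison in this package goes through the small primitives
here so that the treatment of ambiguity codes and gaps is uniform:
unambiguous bases are {A, C, G, T}; every other symbol (ambiguity code or
gap) is excluded from site-wise comparisons (pairwise deletion).
"""

from __future__ import annotations

BASES = frozenset("ACGT")
GAP = "-"

#: symbol -> set of unambiguous bases it stands for
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

ALPHABET = frozenset(EXPANSION) | {GAP}

#: set of bases -> the (unique) IUPAC symbol covering exactly that set
CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in EXPANSION.items()}


def expand(symbol: str) -> frozenset[str]:
    """Return the set of bases a symbol stands for (empty set for a gap)."""
    if symbol == GAP:
        return frozenset()
    return EXPANSION[symbol]


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Return the IUPAC symbol covering exactly *bases*."""
    return CODE_FOR[frozenset(bases)]


def is_base(symbol: str) -> bool:
    return symbol in BASES


def is_ambiguous(symbol: str) -> bool:
    """True for 2-, 3- or 4-base degenerate symbols (including N)."""
    return symbol in EXPANSION and len(EXPANSION[symbol]) > 1


def compare_sequences(a: str, b: str) -> tuple[int, int]:
    """Site-wise comparison under pairwise deletion.

    Returns ``(n_diff, n_comparable)`` where a site is comparable only when
    both symbols are unambiguous bases.
    """
    n_diff = 0
    n_comp = 0
    for x, y in zip(a, b, strict=True):
        if x in BASES and y in BASES:
            n_comp += 1
            if x != y:
                n_diff += 1
    return n_diff, n_comp


def hamming_distance(a: str, b: str) -> int:
    """Number of comparable sites at which two equal-length sequences differ."""
    return compare_sequences(a, b)[0]
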