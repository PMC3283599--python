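"""IUPAC nucleotide ambiguity codes and set arithmetic.

Consensus calling and numt screening both treat an ambiguity code as the
*set* of bases it denotes: R = {A, G}, Y = {C, T}, N = {A, C, G, T}, and so
on.  Two positions are *compatible* when their base sets intersect; the
distance helpers below ignore compatible ambiguity so that damage-derived
R/Y codes never inflate a divergence estimate.
"""

from __future__ import annotations

from typing import Iterable

#: ambiguity letter -> frozenset of unambiguous bases
CODE_TO_SET: dict[str, frozenset[str]] = {
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

SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in CODE_TO_SET.items()}

BASES = ("A", "C", "G", "T")


def base_set(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC letter (case-insensitive)."""
    try:
        return CODE_TO_SET[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases: Iterable[str]) -> str:
    """IUPAC letter for a non-empty set of unambiguous bases."""
    s = frozenset(b.upper() for b in bases)
    try:
        return SET_TO_CODE[s]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(s)}") from None


def compatible(a: str, b: str) -> bool:
    """True when the two codes' base sets intersect."""
    return bool(base_set(a) & base_set(b))


def intersect(a: str, b: str) -> str | None:
    """IUPAC code of the set intersection, or None when disjoint."""
    s = base_set(a) & base_set(b)
    return SET_TO_CODE[s] if s else None


def union(a: str, b: str) -> str:
    """IUPAC code of the set union."""
    return SET_TO_CODE[base_set(a) | base_set(b)]


def p_distance(a: str, b: str) -> float:
    """Proportion of incompatible sites between two equal-length sequences.

    Sites where the IUPAC sets intersect count as matches (an R is not a
    mismatch against an A); sites where either sequence is fully missing
    (N or gap) are excluded from the denominator.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    diff = 0
    comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-.?" or y in "-.?" or x == "N" or y == "N":
            continue
        comparable += 1
        if not compatible(x, y):
            diff += 1
    return diff / comparable if comparable else 0.0


def identity(a: str, b: str) -> float:
    """1 − p_distance over the comparable sites."""
    return 1.0 - p_distance(a, b)
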