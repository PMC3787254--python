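"""IUPAC nucleotide ambiguity codes and small sequence helpers."""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
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

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-.",
    "TGCAAYRSWMKVHDBN-.",
)

GAP_CHARS = frozenset("-.")


def normalize_bases(seq: str) -> str:
    """Uppercase and map U to T. Idempotent."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC_SETS for c in seq.upper())


def iupac_match(code: str, base: str) -> bool:
    """True if *base* is one of the concrete bases encoded by *code*.

    An N (or any code) in the query position matches the bases in its set;
    an N in the target base position is in no code's set except via N→set
    lookup, so callers decide target-side semantics.
    """
    s = IUPAC_SETS.get(code)
    return s is not None and base in s


def iupac_intersect(a: str, b: str) -> bool:
    """True if the IUPAC sets of the two characters share a base."""
    sa = IUPAC_SETS.get(a)
    sb = IUPAC_SETS.get(b)
    return bool(sa and sb and (sa & sb))
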