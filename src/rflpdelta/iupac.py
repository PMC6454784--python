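"""IUPAC nucleotide alphabet: bitmask encoding, complements, set semantics.

Each IUPAC symbol denotes a set of the four bases. Encoding the set as a
4-bit mask makes "do these two symbols share a base?" a single AND, which
is the compatibility rule used for degenerate-primer matching: a primer
symbol matches a template symbol iff their base sets intersect.
"""

from __future__ import annotations

#: base-set bitmask per IUPAC symbol (A=1, C=2, G=4, T=8)
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4,          # puRine
    "Y": 2 | 8,          # pYrimidine
    "S": 2 | 4,          # Strong
    "W": 1 | 8,          # Weak
    "K": 4 | 8,          # Keto
    "M": 1 | 2,          # aMino
    "B": 2 | 4 | 8,      # not A
    "D": 1 | 4 | 8,      # not C
    "H": 1 | 2 | 8,      # not G
    "V": 1 | 2 | 4,      # not T
    "N": 1 | 2 | 4 | 8,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_CHARS = frozenset(IUPAC_MASK)


class InvalidNucleotideError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid IUPAC character {char!r} at position {position} in {context}"
        )


def validate_iupac(sequence: str, context: str = "sequence") -> str:
    """Uppercase *sequence* and raise :class:`InvalidNucleotideError` on the
    first non-IUPAC character."""
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CHARS:
            raise InvalidNucleotideError(ch, i, context)
    return seq


def encode(sequence: str, context: str = "sequence") -> list[int]:
    """Encode a validated sequence as a list of base-set bitmasks."""
    seq = validate_iupac(sequence, context)
    return [IUPAC_MASK[ch] for ch in seq]


def reverse_complement(sequence: str) -> str:
    """Reverse complement honouring ambiguity codes (e.g. K -> M)."""
    seq = validate_iupac(sequence)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def compatible(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC symbols intersect."""
    return bool(IUPAC_MASK[a.upper()] & IUPAC_MASK[b.upper()])
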