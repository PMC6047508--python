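"""Small DNA utilities shared across the pipeline: reverse complement,
IUPAC ambiguity handling and alphabet validation."""

from __future__ import annotations

# IUPAC nucleotide codes -> set of plain bases they cover
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
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

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

READ_ALPHABET = frozenset("ACGTN")
IUPAC_ALPHABET = frozenset(IUPAC_TO_BASES) | {"-"}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement; handles IUPAC ambiguity codes and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """Minimal IUPAC code covering a non-empty set of plain bases."""
    key = frozenset(bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"not a set of plain bases: {sorted(key)}") from None


def validate_read_sequence(seq: str) -> None:
    bad = set(seq) - READ_ALPHABET
    if bad:
        raise ValueError(f"read sequence contains non-{{A,C,G,T,N}} characters: {sorted(bad)}")


def validate_iupac_sequence(seq: str) -> None:
    bad = set(seq.upper()) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-IUPAC characters: {sorted(bad)}")


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc
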