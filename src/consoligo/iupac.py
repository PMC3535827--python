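"""IUPAC-IUB nucleotide ambiguity codes and low-level sequence utilities.

Each of the 15 one-letter codes stands for a set of concrete bases
(R = A/G, Y = C/T, ... N = any).  A degenerate oligo is synthesised as an
equimolar mixture of every concrete expansion, so the number of expansions
(the *degeneracy*) is the product of per-position base-set sizes.
"""

from __future__ import annotations

CODE_TO_BASES: dict[str, frozenset[str]] = {
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

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

GAP = "-"
CODES = frozenset(CODE_TO_BASES)


def bases(code: str) -> frozenset[str]:
    """Concrete base set covered by one IUPAC symbol."""
    try:
        return CODE_TO_BASES[code]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def is_degenerate(code: str) -> bool:
    """True when the symbol covers two or more bases."""
    return len(bases(code)) > 1


def degenerate_count(seq: str) -> int:
    """Number of positions whose base set has size >= 2."""
    return sum(1 for c in seq if len(bases(c)) > 1)


def degeneracy(seq: str) -> int:
    """Number of distinct concrete sequences the oligo represents."""
    d = 1
    for c in seq:
        d *= len(bases(c))
    return d


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet.

    Gap characters cannot be complemented and raise ``ValueError``.
    """
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None
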