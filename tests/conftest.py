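import itertools
import random

import pytest

from consoligo import build_consensus, make_alignment

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def cons_from_codes(codes: str):
    """Consensus whose code string equals ``codes`` (single-sequence mode)."""
    return build_consensus(make_alignment([codes]))


def expansions(seq: str):
    """All concrete expansions of a degenerate oligo (test-side oracle)."""
    return ("".join(t) for t in itertools.product(*(IUPAC_SETS[c] for c in seq)))


def wallace_oracle(seq: str) -> int:
    """Closed-form Wallace rule, written independently of the package."""
    return sum(4 if c in "CG" else 2 for c in seq)


def random_degenerate_oligo(rng: random.Random, min_len=8, max_len=25,
                            max_expansions=64) -> str:
    """Random IUPAC oligo whose total degeneracy stays enumerable."""
    n = rng.randint(min_len, max_len)
    seq, deg = [], 1
    for _ in range(n):
        if deg < max_expansions and rng.random() < 0.25:
            c = rng.choice("RYSWKMBDHVN")
        else:
            c = rng.choice("ACGT")
        if deg * len(IUPAC_SETS[c]) > max_expansions:
            c = rng.choice("ACGT")
        deg *= len(IUPAC_SETS[c])
        seq.append(c)
    return "".join(seq)


@pytest.fixture
def rng():
    return random.Random(20240917)
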