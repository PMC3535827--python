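"""Degenerate consensus construction with a per-position conservation track.

Each alignment column is collapsed to the IUPAC symbol covering every base
observed in it (optionally ignoring rare bases via ``maf_cutoff``), together
with a conservation fraction used downstream to filter primer sites.

Conservation at a column is the frequency of the modal (most common) non-gap
symbol among the non-gap characters: 1.0 exactly when all non-gap characters
agree.  Input ambiguity codes are expanded when deciding which bases the
consensus must cover (an input ``R`` is evidence for both A and G) but a
symbol only feeds the conservation numerator through its own literal count,
so ambiguous evidence never inflates conservation.  The fraction of symbols
matching the consensus code itself is tracked separately (``code_match``).

Gap policy: any column containing a gap is flagged ``has_gap`` and its code
is forced to ``N``; the search layer refuses to place oligos across such
columns unless explicitly allowed.  An all-gap column gets depth 0 and
conservation 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .alignment import Alignment
from .errors import AllGapColumnError
from .iupac import BASES_TO_CODE, CODE_TO_BASES, GAP, bases

_SYMBOLS = "ACGTRYSWKMBDHVN" + GAP
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP_IDX = _SYM_INDEX[GAP]

# ascii byte -> symbol index lookup for vectorized column counting
_ASCII_TO_IDX = np.full(256, -1, dtype=np.int8)
for _c, _i in _SYM_INDEX.items():
    _ASCII_TO_IDX[ord(_c)] = _i


@dataclass(frozen=True)
class ConsensusPosition:
    """One consensus column.

    modal_base is the concrete base with the strongest support (ties broken
    alphabetically); it is used as the expansion for nearest-neighbor Tm on
    degenerate oligos.  code_match is the fraction of non-gap symbols equal
    to ``code`` itself, an alternative conservation reading exposed in the
    track export.
    """

    code: str
    conservation: float
    has_gap: bool
    depth: int
    modal_base: str | None = None
    code_match: float = 0.0


@dataclass(frozen=True)
class ConsensusSequence:
    positions: tuple[ConsensusPosition, ...]
    source: str  # "alignment" | "single_sequence"

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def sequence(self) -> str:
        """The degenerate consensus as an IUPAC string."""
        return "".join(p.code for p in self.positions)

    def slice(self, start: int, end: int) -> tuple[ConsensusPosition, ...]:
        return self.positions[start:end]

    def modal_string(self, start: int, end: int) -> str:
        """Concrete modal expansion of [start, end); ties and empty columns
        fall back to the alphabetically first base of the code's set."""
        out = []
        for p in self.positions[start:end]:
            out.append(p.modal_base if p.modal_base is not None else min(bases(p.code)))
        return "".join(out)

    def to_fasta(self, path: str | Path, name: str = "consensus") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    def to_track_tsv(self, path: str | Path) -> None:
        """Per-position track: 1-based position, code, conservation (modal
        fraction), exact-match-to-code fraction, depth, gap flag."""
        with open(path, "w") as fh:
            fh.write("position\tcode\tconservation\tcode_match\tdepth\thas_gap\n")
            for i, p in enumerate(self.positions, start=1):
                fh.write(
                    f"{i}\t{p.code}\t{p.conservation:.4f}\t{p.code_match:.4f}"
                    f"\t{p.depth}\t{int(p.has_gap)}\n"
                )


def _included_bases(counts: dict[str, int], maf_cutoff: float) -> frozenset[str]:
    """Bases the consensus code must cover, given non-gap symbol counts.

    A base is included when its expanded frequency (fraction of non-gap
    characters whose base set contains it) exceeds maf_cutoff.  If the cutoff
    excludes everything, the maximally supported base(s) are kept so a code
    always exists.
    """
    depth = sum(counts.values())
    weight = dict.fromkeys("ACGT", 0)
    for sym, n in counts.items():
        for b in CODE_TO_BASES[sym]:
            weight[b] += n
    included = {b for b, w in weight.items() if w > 0 and w / depth > maf_cutoff}
    if not included:
        top = max(weight.values())
        included = {b for b, w in weight.items() if w == top and w > 0}
    return frozenset(included)


def _check_cutoff(maf_cutoff: float) -> None:
    if not 0.0 <= maf_cutoff < 0.5:
        raise ValueError(f"maf_cutoff must be in [0, 0.5), got {maf_cutoff}")


def column_code(column: Iterable[str], maf_cutoff: float = 0.0) -> str:
    """IUPAC code for one alignment column (gaps ignored).

    With the default cutoff 0 every observed base is covered, so the code's
    base set is exactly the union of the column's expanded base sets.
    """
    _check_cutoff(maf_cutoff)
    counts: Counter[str] = Counter()
    for c in column:
        if c == GAP:
            continue
        if c not in CODE_TO_BASES:
            raise ValueError(f"not an IUPAC nucleotide code: {c!r}")
        counts[c] += 1
    if not counts:
        raise AllGapColumnError("column contains only gap characters")
    return BASES_TO_CODE[_included_bases(counts, maf_cutoff)]


def build_consensus(aln: Alignment, maf_cutoff: float = 0.0) -> ConsensusSequence:
    """Collapse an alignment into a degenerate consensus.

    Record order never matters; a single-record alignment reproduces its
    input sequence with conservation 1.0 everywhere (``single_sequence``
    mode, for manually curated consensuses).
    """
    _check_cutoff(maf_cutoff)
    n, length = aln.n_records, aln.length

    idx = np.empty((n, length), dtype=np.int8)
    for i, s in enumerate(aln.sequences()):
        idx[i] = _ASCII_TO_IDX[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    counts = np.zeros((length, len(_SYMBOLS)), dtype=np.int64)
    cols = np.arange(length)
    for i in range(n):
        counts[cols, idx[i]] += 1

    positions = []
    for j in range(length):
        row = counts[j]
        has_gap = row[_GAP_IDX] > 0
        symcounts = {
            _SYMBOLS[k]: int(row[k]) for k in range(len(_SYMBOLS) - 1) if row[k]
        }
        depth = sum(symcounts.values())
        if depth == 0:
            positions.append(
                ConsensusPosition("N", 0.0, True, 0, modal_base=None, code_match=0.0)
            )
            continue
        conservation = max(symcounts.values()) / depth
        weight = dict.fromkeys("ACGT", 0)
        for sym, cnt in symcounts.items():
            for b in CODE_TO_BASES[sym]:
                weight[b] += cnt
        modal_base = min(b for b, w in weight.items() if w == max(weight.values()))
        if has_gap:
            code = "N"
        else:
            code = BASES_TO_CODE[_included_bases(symcounts, maf_cutoff)]
        positions.append(
            ConsensusPosition(
                code=code,
                conservation=conservation,
                has_gap=has_gap,
                depth=depth,
                modal_base=modal_base,
                code_match=symcounts.get(code, 0) / depth,
            )
        )
    source = "single_sequence" if n == 1 else "alignment"
    return ConsensusSequence(positions=tuple(positions), source=source)
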