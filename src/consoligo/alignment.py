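"""FASTA input: multiple sequence alignments and single-sequence consensus mode.

The input is a standard FASTA file holding either an alignment (all records
the same length, gaps written as ``-``) or a single, possibly degenerate,
sequence that will be used directly as the consensus.  RNA input is accepted
and stored internally as DNA (``U`` mapped to ``T``); the report layer maps
``T`` back to ``U`` when the run was declared RNA.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlignmentShapeError, AlphabetError, EmptyInputError
from .iupac import CODES, GAP

log = logging.getLogger(__name__)

_ALLOWED = CODES | {GAP}
_ALPHABETS = ("DNA", "RNA")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record after normalization (uppercase, U mapped to T)."""

    id: str
    seq: str
    description: str = ""


@dataclass(frozen=True)
class Alignment:
    """An ordered, validated set of equal-length sequences.

    A one-record Alignment is the "single sequence used as consensus" case;
    gaps are only meaningful (and only permitted) with two or more records.
    """

    records: tuple[SequenceRecord, ...]
    alphabet: str = "DNA"

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def column(self, i: int) -> list[str]:
        return [r.seq[i] for r in self.records]


def _normalize(raw: str, rec_id: str, alphabet: str) -> str:
    s = str(raw).upper()
    if alphabet == "RNA":
        s = s.replace("U", "T")
    for col, c in enumerate(s):
        if c not in _ALLOWED:
            raise AlphabetError(
                f"record {rec_id!r}, column {col + 1}: illegal character {c!r}"
            )
    return s


def make_alignment(
    seqs: Sequence[str],
    ids: Iterable[str] | None = None,
    alphabet: str = "DNA",
    descriptions: Iterable[str] | None = None,
) -> Alignment:
    """Build and validate an :class:`Alignment` from raw strings.

    Shared by :func:`read_alignment` and the synthetic-alignment generator so
    every Alignment in the package passes through the same invariant checks.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be one of {_ALPHABETS}, got {alphabet!r}")
    seqs = list(seqs)
    if not seqs:
        raise EmptyInputError("input contains no sequence records")
    ids = list(ids) if ids is not None else [f"seq{i + 1}" for i in range(len(seqs))]
    descriptions = list(descriptions) if descriptions is not None else [""] * len(seqs)

    records = []
    for rec_id, desc, raw in zip(ids, descriptions, seqs):
        s = _normalize(raw, rec_id, alphabet)
        if not s:
            raise AlignmentShapeError(f"record {rec_id!r} is empty")
        records.append(SequenceRecord(id=rec_id, seq=s, description=desc))

    ref = records[0]
    for rec in records[1:]:
        if len(rec.seq) != len(ref.seq):
            raise AlignmentShapeError(
                f"record {rec.id!r} has length {len(rec.seq)}, "
                f"expected {len(ref.seq)} (as in record {ref.id!r})"
            )
    if len(records) == 1 and GAP in records[0].seq:
        raise AlphabetError(
            f"record {records[0].id!r} contains gap characters but is the only "
            "record; gaps are only meaningful in a multiple alignment"
        )
    dupes = [i for i, n in Counter(r.id for r in records).items() if n > 1]
    if dupes:
        log.warning("duplicate record ids in input: %s", ", ".join(sorted(dupes)))
    return Alignment(records=tuple(records), alphabet=alphabet)


def read_alignment(path: str | Path, alphabet: str = "DNA") -> Alignment:
    """Read a FASTA file as an alignment (or single consensus sequence).

    Wrapped and unwrapped FASTA, LF and CRLF line endings, and lowercase
    sequences are all accepted; record ids are the header token before the
    first whitespace.  Deterministic: the same bytes always yield an equal
    Alignment, with record order preserved.
    """
    path = Path(path)
    recs = list(SeqIO.parse(str(path), "fasta"))
    return make_alignment(
        seqs=[str(r.seq) for r in recs],
        ids=[r.id for r in recs],
        alphabet=alphabet,
        descriptions=[r.description for r in recs],
    )


def write_alignment(aln: Alignment, path: str | Path, width: int = 70) -> None:
    """Write the alignment back to FASTA (round-trips with read_alignment)."""
    with open(path, "w") as fh:
        for rec in aln.records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
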