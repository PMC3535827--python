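"""Synthetic alignments with planted conserved blocks.

Generates test alignments with a known ground truth: a random ancestor is
copied ``n_seqs`` times, background positions mutate independently with a
per-site substitution probability (uniform over the three alternative bases,
no transition bias) and may receive single-column gaps, while positions
inside the planted conserved blocks are never touched.  This emulates the
situation the tool is built for -- divergent sequence sets that still share
conserved primer-length islands -- without modelling a phylogeny or rate
heterogeneity.

All randomness flows through one seeded numpy generator, so the same spec
always produces byte-identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment, make_alignment
from .errors import ParameterError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STRESS_BLOCK_MOTIF = "ACGTACGTACGTACGTACGTACGTA"  # 25 nt, Td(20-mer prefix) = 60


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic alignment.

    conserved_blocks are 0-based half-open intervals that are copied
    unchanged into every sequence; block_sequences, if given, overwrite the
    ancestor inside each block (same order, matching lengths), which lets a
    caller plant primer sites with a known Td.
    """

    n_seqs: int
    length: int
    conserved_blocks: tuple[tuple[int, int], ...] = ()
    background_divergence: float = 0.3
    indel_prob: float = 0.0
    seed: int = 0
    block_sequences: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_seqs < 1 or self.length < 1:
            raise ParameterError("n_seqs and length must be positive")
        if not 0.0 <= self.background_divergence <= 1.0:
            raise ParameterError("background_divergence must be in [0, 1]")
        if not 0.0 <= self.indel_prob <= 1.0:
            raise ParameterError("indel_prob must be in [0, 1]")
        last = 0
        for start, end in sorted(self.conserved_blocks):
            if not 0 <= start < end <= self.length:
                raise ParameterError(
                    f"block ({start}, {end}) outside [0, {self.length})"
                )
            if start < last:
                raise ParameterError("conserved blocks overlap")
            last = end
        if self.block_sequences is not None:
            if len(self.block_sequences) != len(self.conserved_blocks):
                raise ParameterError("one block_sequence per conserved block required")
            for (start, end), s in zip(self.conserved_blocks, self.block_sequences):
                if len(s) != end - start:
                    raise ParameterError(
                        f"block sequence length {len(s)} != block span {end - start}"
                    )


def generate_alignment(
    spec: SynthSpec,
) -> tuple[Alignment, tuple[tuple[int, int], ...]]:
    """Generate the alignment described by ``spec``.

    Returns the alignment and the planted-block ground truth (0-based
    half-open, same convention as search coordinates).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.integers(0, 4, size=spec.length)
    mask = np.zeros(spec.length, dtype=bool)
    for start, end in spec.conserved_blocks:
        mask[start:end] = True
    if spec.block_sequences is not None:
        lut = {b: i for i, b in enumerate("ACGT")}
        for (start, end), s in zip(spec.conserved_blocks, spec.block_sequences):
            ancestor[start:end] = [lut[c] for c in s.upper()]

    seqs = []
    for _ in range(spec.n_seqs):
        s = ancestor.copy()
        mutate = (rng.random(spec.length) < spec.background_divergence) & ~mask
        shift = rng.integers(1, 4, size=spec.length)
        s[mutate] = (s[mutate] + shift[mutate]) % 4
        chars = _BASES[s].copy()
        gap = (rng.random(spec.length) < spec.indel_prob) & ~mask
        chars[gap] = ord("-")
        seqs.append(chars.tobytes().decode("ascii"))
    aln = make_alignment(seqs, ids=[f"synth{i + 1}" for i in range(spec.n_seqs)])
    return aln, tuple(spec.conserved_blocks)


def planted_pair_spec(
    n_pairs: int = 3,
    n_seqs: int = 16,
    window: int = 400,
    slide: int = 20,
    block_len: int = 25,
    spacing: int = 200,
    background_divergence: float = 0.5,
    indel_prob: float = 0.0,
    seed: int = 0,
    designed_blocks: bool = False,
) -> tuple[SynthSpec, tuple[tuple[int, int], ...]]:
    """Spec with n_pairs planted primer-site pairs whose geometry fits the
    windowed search: each pair is a forward block at a multiple of ``slide``
    and a reverse block ending exactly one window later.

    Returns the spec and the product starts/ends of each planted pair
    ((p, p + window), 0-based half-open).  With ``designed_blocks`` every
    block carries the fixed stress motif (in band at default Td limits);
    otherwise block content is random ancestor sequence.
    """
    stride = window + spacing
    stride += (-stride) % slide  # pair starts stay on the sliding grid
    first = slide  # keep pairs off the very edge
    length = first + (n_pairs - 1) * stride + window + spacing
    blocks: list[tuple[int, int]] = []
    pairs: list[tuple[int, int]] = []
    for i in range(n_pairs):
        p = first + i * stride
        blocks.append((p, p + block_len))
        blocks.append((p + window - block_len, p + window))
        pairs.append((p, p + window))
    block_seqs = (
        tuple(STRESS_BLOCK_MOTIF[:block_len] for _ in blocks) if designed_blocks else None
    )
    spec = SynthSpec(
        n_seqs=n_seqs,
        length=length,
        conserved_blocks=tuple(blocks),
        background_divergence=background_divergence,
        indel_prob=indel_prob,
        seed=seed,
        block_sequences=block_seqs,
    )
    return spec, tuple(pairs)


def hcv_like_stress(
    seed: int = 0,
) -> tuple[Alignment, tuple[tuple[int, int], ...]]:
    """Large-scale stress preset: 61 sequences x 10,000 nt at ~30% background
    divergence with five planted primer-site pairs (window 400, designed
    blocks so the pairs are recoverable at default parameters).

    A synthetic stand-in, at matching problem size, for running the tool on
    dozens of aligned full-length viral genomes.
    """
    window, block_len = 400, 25
    starts = (400, 2400, 4400, 6400, 8400)
    blocks: list[tuple[int, int]] = []
    pairs: list[tuple[int, int]] = []
    for p in starts:
        blocks.append((p, p + block_len))
        blocks.append((p + window - block_len, p + window))
        pairs.append((p, p + window))
    spec = SynthSpec(
        n_seqs=61,
        length=10_000,
        conserved_blocks=tuple(blocks),
        background_divergence=0.30,
        indel_prob=0.0,
        seed=seed,
        block_sequences=tuple(STRESS_BLOCK_MOTIF for _ in blocks),
    )
    aln, _ = generate_alignment(spec)
    return aln, tuple(pairs)


def write_truth_tsv(
    blocks: tuple[tuple[int, int], ...], path: str | Path
) -> None:
    """Write planted-block ground truth as TSV (1-based inclusive, stated in
    the header to match the report convention)."""
    with open(path, "w") as fh:
        fh.write("# planted conserved blocks; coordinates 1-based inclusive\n")
        fh.write("block_start\tblock_end\n")
        for start, end in blocks:
            fh.write(f"{start + 1}\t{end}\n")
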