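# consoligo

Degenerate PCR primer and probe design from multiple sequence alignments.

Designing primers that hybridize across a *diverse* set of target sequences
— typical in clinical and environmental microbiology, where a single assay
must detect many strains of a virus or bacterium — is mostly a search for
conserved regions. `consoligo` takes a multiple sequence alignment (or a
single curated sequence), collapses it column-by-column into an
**IUPAC-degenerate consensus** that keeps every observed base (R = A/G,
Y = C/T, …, N = any), and then scans that consensus for oligos that are
conserved enough to work as primers or hydrolysis probes.

## Method

1. **Consensus.** Each alignment column becomes the IUPAC code covering every
   base observed in it (optionally ignoring bases at or below a minor-allele
   frequency cutoff), with a conservation value — the modal-base fraction
   among non-gap characters. Columns containing alignment gaps are flagged
   and excluded from primer placement by default.
2. **Search.** Either
   - *windowed* (`design`): a window whose size equals the desired PCR
     product slides along the consensus by a step (default 20 nt). The
     forward primer starts at the window's first position, the reverse
     primer's binding site ends at its last, so the product size equals the
     window size. Short windows (< 150 nt, `--probe`) give real-time PCR
     primer/probe sets; long windows (> 200 nt) give sequencing amplicons.
   - *all-oligos* (`scan`): every valid oligo anywhere on the consensus,
     both strands, with coordinates — for assembling a system by hand when
     the windowed search finds nothing.
3. **Oligo validity.** Length within bounds (default 18–25 nt); at most 3
   degenerate positions; **zero** degenerate positions in the 3′-terminal
   clamp (default 3 nt) — a 3′ mismatch aborts extension; Wallace-rule
   dissociation temperature range intersecting the requested band
   (default 50–65 °C); no gap columns spanned.
4. **Thermodynamics.** Every oligo is reported with its GC-content range and
   Wallace-rule dissociation temperature

   *T*<sub>d</sub> = 2 °C · (#A + #T) + 4 °C · (#C + #G),

   computed as an exact min–max range over all concrete expansions of a
   degenerate oligo. Oligos ≥ 14 nt additionally get a two-state
   nearest-neighbor melting temperature (unified SantaLucia 1998 parameters,
   monovalent-salt entropy correction; evaluated on the modal expansion for
   degenerate oligos and flagged as such).

## Worked example

```
$ consoligo fixtures --out-fasta demo.fasta --seed 5 --n-seqs 10 \
      --length 520 --divergence 0.6 --blocks 21-45,396-420
$ consoligo design --in demo.fasta --out - --window 400 --slide 20 \
      --td-min 36 --td-max 100 | grep -v '^#' | cut -f1-8,11-12
role	sequence	start	end	strand	length	degenerate_count	degeneracy	td_min	td_max
forward_primer	AGTACCCTATTTACGCGGGATGT	21	43	fwd	23	0	1	68.0	68.0
reverse_primer	ATCGGCTTTCTCTCGGACTAGTT	398	420	rev	23	0	1	68.0	68.0
```

The fixture plants two perfectly conserved 25-nt blocks (positions 21–45 and
396–420, 1-based) in an otherwise 60%-divergent 10-sequence alignment; the
windowed search recovers a primer pair inside exactly those blocks: the
forward primer starts at the window's first position (21) and the reverse
primer's binding site ends at its last (420), delimiting the 400-nt product.
Each row shows the degenerate 5′→3′ sequence, its 1-based inclusive
coordinates on the consensus, strand, the degenerate-position count, the
number of concrete expansions, and the Wallace *T*<sub>d</sub> range (a
single point here because the planted sites are non-degenerate).

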