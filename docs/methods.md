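# Methods

## Problem and model

The tool searches for PCR primers and hydrolysis probes that hybridize
across a diverse set of homologous sequences. The model is deliberately
simple: conservation is the only signal. An alignment is collapsed to a
degenerate consensus, and an oligo is acceptable wherever the consensus is
concrete enough — degeneracy bounded overall and absent at the 3′ end —
and its Wallace-rule dissociation temperature falls in a user band. No
secondary-structure, hairpin, primer-dimer or cross-specificity screening
is attempted; those belong to downstream tools.

## Consensus construction

For each column the non-gap characters are tallied. Input ambiguity codes
are first expanded to their base sets when deciding coverage — an input `R`
is evidence that both A and G occur — so the consensus code is the IUPAC
symbol for exactly the set of bases whose expanded column frequency exceeds
`maf_cutoff` (default 0: every observed base is covered; the degeneracy is
instead capped later, at the oligo level). If a cutoff would exclude every
base, the maximally supported base(s) are kept so a code always exists.

Conservation is reported as the modal-symbol fraction among non-gap
characters: 1.0 exactly when all non-gap characters agree. Ambiguity
symbols count toward the denominator and only toward the numerator through
their own literal counts, so ambiguous evidence never inflates
conservation. Because the alternative reading — fraction of characters
equal to the consensus code itself — is equally defensible, both are
emitted in the conservation track (`conservation` and `code_match`).

Gap policy: the alignment literature gives no principled way to place a
primer across an indel column, so any column containing a gap is flagged
`has_gap`, its code forced to `N`, and oligos spanning it rejected unless
`--allow-gap-columns` is given. An all-gap column has depth 0 and
conservation 0. A single-sequence input is used verbatim as the consensus
(conservation 1.0 everywhere), supporting manually curated consensuses.

## Oligo validity

An oligo (a consensus substring, or its reverse complement for the minus
strand; sequences are always written 5′→3′) is valid when all of:

| rule | default | meaning |
|---|---|---|
| length | 18–25 nt | synthesis- and kinetics-practical primer lengths |
| max_degenerate | 3 | at most 3 variable positions per oligo |
| three_prime_clamp | 3 nt | zero variable sites at the 3′ end (mismatches there abort extension); applied to probes too, relaxable with `--probe-no-clamp` since hydrolysis probes are not extended |
| td_band | 50–65 °C | Wallace-Td *range* must intersect the band — with degenerate oligos a point test is ill-defined, so range-intersection semantics are used |
| gap_column | on | no `has_gap` column spanned |
| min_conservation | 0 | optional per-position conservation floor |

With `maf_cutoff = 0` a non-degenerate clamp position is automatically a
fully conserved column, so the clamp implements "zero variable sites at the
3′ end" exactly.

## Search

*Windowed mode.* The window size equals the desired product size (default
150 nt in probe mode — real-time PCR amplicons are classically < 150 nt —
and 400 nt otherwise, a convenient Sanger length; both are this package's
defaults, not community standards). Windows start at multiples of the
sliding value (default 20). The forward primer is anchored at the window
start and the reverse primer's binding site at the window end, so
`product_len == window_size`; `--anchor-slack N` lets either primer shift
inward up to N nt. A probe must bind strictly between the primers,
overlapping neither, on the forward strand by default
(`--probe-both-strands` relaxes this). One set per window is reported — the
best candidate per role — unless `--all-candidates` asks for every
combination; identical sets found by overlapping windows are de-duplicated.

Candidate ranking is a lexicographic score: fewer degenerate positions,
then Td-range midpoint closest to the center of the requested band, then
longer oligo, then smaller start, then strand. The last keys make the order
total, hence the output deterministic.

*All-oligos mode.* Every substring with length in bounds is tested on both
strands and all valid oligos are reported sorted by (start, length,
strand). Coordinates are 0-based half-open internally and 1-based inclusive
in every user-facing file.

## Thermodynamics

Wallace rule: Td = 2·(#A+#T) + 4·(#C+#G) °C, reported for every oligo. For
degenerate oligos the min/max over all concrete expansions is reported as a
range; because the formula is positionwise additive, per-position extremes
sum to the true expansion extremes (verified against brute-force
enumeration in tests). The same argument yields exact GC-content ranges (a
position is guaranteed GC iff its base set ⊆ {G,C}).

Nearest-neighbor Tm: two-state model with the unified SantaLucia 1998
(Allawi & SantaLucia 1997) ΔH/ΔS table, terminal initiation terms, the
self-complementarity entropy correction, and the entropy salt correction
ΔS += 0.368·(N−1)·ln[Na⁺]. Defaults: 50 mM monovalent salt, 0.25 µM per
strand (two-state factor CT/4). It is reported *in addition to* Td for
oligos ≥ 14 nt — the conventional ceiling of Wallace-rule validity — never
instead of it; for a degenerate oligo it is evaluated on the modal
expansion (most supported base per position, ties alphabetical) and flagged
`tm_on_modal` in the report. The implementation is cross-checked in the
test suite against an independent implementation of the same parameter set.

## Synthetic data generator

`SynthSpec`/`generate_alignment` draw a uniform-random ancestor, copy it
`n_seqs` times, and mutate background positions independently with
probability `background_divergence` (uniform over the three alternatives —
no transition/transversion bias, no phylogeny, no rate heterogeneity) plus
optional single-column gaps; planted conserved blocks are never touched and
may carry caller-specified sequence. Defaults used in tests — 16 sequences,
50% background divergence — are chosen so that background columns are
almost surely degenerate while planted blocks stay perfectly conserved,
separating signal from noise cleanly. This emulates what the tool needs
from real data (conserved islands in a divergent alignment) but not its
correlation structure: real alignments have tree-shaped relatedness,
indel blocks and locally varying divergence, so passing planted-recovery
tests demonstrates correctness of the search logic, not field performance.

The stress preset (61 sequences × 10,000 nt, 30% divergence, five planted
primer pairs at window-400 geometry) exercises the full pipeline at the
scale of dozens of aligned full-length viral genomes; it completes in a few
seconds on one CPU, and its runtime is logged but never asserted.

Planted-recovery tests and the acceptance script widen the Td band to
36–100 °C: planted block content is random there, and the property under
test is site recovery, not Td filtering.

## Numerical and degenerate-input choices

- All coordinates internal 0-based half-open; reports 1-based inclusive.
- Temperatures and GC percentages are printed with one decimal; reports are
  byte-identical across reruns of the same input and parameters.
- Empty search results are success (exit 0) with a logged warning and a
  header-only report.
- A window larger than the consensus is a usage error (exit 2); unreadable
  or ill-formed FASTA is an input error (exit 1).
- Duplicate FASTA ids load with a warning; record order never affects any
  output (verified by property test).

## Known limitations

- No secondary-structure, dimer or specificity screening.
- The Wallace rule is an approximation for short oligos only; the NN Tm
  ignores Mg²⁺ and dNTP effects.
- Conservation weighting is flat across sequences: over-represented clades
  in the input alignment bias the consensus, since no phylogenetic
  down-weighting is applied.
- Windowed primers are anchored to the window frame; sites off the sliding
  grid are only reachable via `--anchor-slack` or the all-oligos mode.
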