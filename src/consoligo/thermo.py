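"""Oligo thermodynamics: GC content, Wallace-rule Td, nearest-neighbor Tm.

The dissociation temperature reported for every oligo is the Wallace rule

    Td = 2 degC * (#A + #T) + 4 degC * (#C + #G)

which is positionwise additive, so for a degenerate oligo the minimum and
maximum over all concrete expansions equal the sums of per-position extremes;
the same argument gives exact GC-content ranges.  For oligos of at least
``nn_min_len`` nucleotides (default 14, the conventional upper bound of the
Wallace rule's validity) a two-state nearest-neighbor melting temperature is
additionally computed; for degenerate oligos it is evaluated on the modal
expansion and flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .iupac import bases, degenerate_count, reverse_complement

R_GAS = 1.987  # cal / (mol K)

# Unified duplex nearest-neighbor parameters (SantaLucia 1998, PNAS 95:1460;
# identical to Allawi & SantaLucia 1997).  dH in kcal/mol, dS in cal/(mol K)
# per stacked dinucleotide, 5'->3' on the top strand.
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# duplex initiation, per terminal base pair
_INIT: dict[str, tuple[float, float]] = {
    "A": (2.3, 4.1),
    "T": (2.3, 4.1),
    "G": (0.1, -2.8),
    "C": (0.1, -2.8),
}
_SYM_CORR_DS = -1.4  # self-complementary duplex entropy correction


def _require_concrete(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = [c for c in seq if c not in "ACGT"]
    if bad:
        raise ValueError(
            f"{op}: sequence contains non-concrete character {bad[0]!r}; "
            "use td_range for degenerate oligos"
        )


def wallace_td(seq: str) -> int:
    """Wallace-rule dissociation temperature of a non-degenerate oligo, degC."""
    _require_concrete(seq, "wallace_td")
    gc = sum(1 for c in seq if c in "GC")
    return 2 * (len(seq) - gc) + 4 * gc


def td_range(seq: str) -> tuple[int, int]:
    """Min and max Wallace Td over all concrete expansions of a degenerate oligo.

    Computed per position (the formula is positionwise additive, so the sums
    of per-position extremes are attained by actual expansions).  Collapses
    to a point exactly when the oligo has no degenerate position.
    """
    if not seq:
        raise ValueError("td_range: empty sequence")
    lo = hi = 0
    for c in seq:
        contrib = {2 if b in "AT" else 4 for b in bases(c)}
        lo += min(contrib)
        hi += max(contrib)
    return lo, hi


def gc_range(seq: str) -> tuple[float, float]:
    """Min and max GC percentage over all concrete expansions.

    A position is guaranteed GC when its base set is within {G, C}; it can
    possibly be GC when the set intersects {G, C}.
    """
    if not seq:
        raise ValueError("gc_range: empty sequence")
    gc = frozenset("GC")
    n_min = sum(1 for c in seq if bases(c) <= gc)
    n_max = sum(1 for c in seq if bases(c) & gc)
    return 100.0 * n_min / len(seq), 100.0 * n_max / len(seq)


def nn_tm(seq: str, na_molar: float = 0.05, oligo_molar: float = 2.5e-7) -> float:
    """Two-state nearest-neighbor melting temperature, degC.

    Parameters
    ----------
    seq : non-degenerate DNA string, length >= 8.
    na_molar : monovalent cation concentration in mol/L (default 50 mM);
        entropy salt correction dS += 0.368 (N-1) ln[Na+].
    oligo_molar : concentration of each strand in mol/L (default 0.25 uM).
        For a non-self-complementary duplex with both strands at this
        concentration the two-state factor is CT/4 = oligo_molar/2; a
        self-complementary oligo uses oligo_molar and the symmetry
        entropy correction.
    """
    _require_concrete(seq, "nn_tm")
    if len(seq) < 8:
        raise ValueError(f"nn_tm: sequence shorter than 8 nt ({len(seq)})")
    if na_molar <= 0 or oligo_molar <= 0:
        raise ValueError("nn_tm: concentrations must be positive")
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT[terminal]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = reverse_complement(pair)
        h, s = _NN[pair]
        dh += h
        ds += s
    if seq == reverse_complement(seq):
        ds += _SYM_CORR_DS
        conc = oligo_molar
    else:
        conc = oligo_molar / 2.0
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return dh * 1000.0 / (ds + R_GAS * math.log(conc)) - 273.15


@dataclass(frozen=True)
class ThermoSummary:
    """Per-oligo thermodynamic report values.

    Ranges are over concrete expansions; they collapse to points for
    non-degenerate oligos.  tm_nn is absent for short oligos; tm_on_modal
    marks an NN Tm computed on the modal expansion of a degenerate oligo.
    """

    length: int
    gc_min: float
    gc_max: float
    td_min: int
    td_max: int
    tm_nn: float | None
    method: str  # "wallace" | "nearest_neighbor"
    tm_on_modal: bool = False


def summarize(
    seq: str,
    modal_seq: str | None = None,
    nn_min_len: int = 14,
    na_molar: float = 0.05,
    oligo_molar: float = 2.5e-7,
) -> ThermoSummary:
    """Full thermodynamic summary of one oligo (Wallace Td range always;
    NN Tm when long enough, on the modal expansion if degenerate)."""
    lo, hi = td_range(seq)
    gmin, gmax = gc_range(seq)
    tm = None
    on_modal = False
    if len(seq) >= nn_min_len:
        if degenerate_count(seq) == 0:
            tm = nn_tm(seq, na_molar, oligo_molar)
        elif modal_seq is not None and degenerate_count(modal_seq) == 0:
            tm = nn_tm(modal_seq, na_molar, oligo_molar)
            on_modal = True
    return ThermoSummary(
        length=len(seq),
        gc_min=gmin,
        gc_max=gmax,
        td_min=lo,
        td_max=hi,
        tm_nn=tm,
        method="nearest_neighbor" if tm is not None else "wallace",
        tm_on_modal=on_modal,
    )
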