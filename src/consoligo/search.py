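"""Conserved-oligo search on the degenerate consensus.

Two search modes:

* ``windowed`` -- slide a window whose size equals the desired PCR product
  along the consensus, stepping by the sliding value.  In each window the
  forward primer starts at the window's first position and the reverse
  primer's binding site ends at the window's last position (so the product
  size equals the window size exactly; ``anchor_slack`` lets primers shift
  inward).  With ``probe`` set, a valid probe oligo must additionally lie
  strictly between the primers (real-time PCR design).
* ``all_oligos`` -- list every valid oligo anywhere on the consensus, both
  strands, with coordinates, for manual assembly of a PCR system.

Validity of an oligo combines the two default conserved-primer criteria --
at most ``max_degenerate`` variable positions overall and zero variable
positions in the 3'-terminal clamp -- with length bounds, a Wallace-Td band
(range-intersection semantics for degenerate oligos), the gap-column policy
and an optional per-position conservation floor.

Coordinates are 0-based half-open internally; the report layer converts to
1-based inclusive.  Oligo sequences are always written 5'->3' (reverse-strand
oligos are the reverse complement of their consensus binding site).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .consensus import ConsensusPosition, ConsensusSequence
from .errors import ParameterError
from .iupac import degeneracy, degenerate_count, reverse_complement
from .thermo import ThermoSummary, summarize, td_range

log = logging.getLogger(__name__)

FORWARD = "fwd"
REVERSE = "rev"
_STRAND_ORDER = {FORWARD: 0, REVERSE: 1}


@dataclass
class SearchParams:
    """Every user-settable search knob, with the tool's defaults.

    window_size defaults to 150 in probe (real-time PCR) mode and 400
    otherwise (Sanger sequencing products); the sliding value defaults
    to 20, the degenerate-position cap to 3 and the 3' clamp to 3
    fully non-degenerate terminal positions.
    """

    mode: str = "windowed"  # "windowed" | "all_oligos"
    window_size: int | None = None
    slide: int = 20
    oligo_min_len: int = 18
    oligo_max_len: int = 25
    max_degenerate: int = 3
    clamp_len: int = 3
    td_min: float = 50.0
    td_max: float = 65.0
    probe: bool = False
    probe_both_strands: bool = False
    probe_no_clamp: bool = False
    allow_gap_columns: bool = False
    min_conservation: float = 0.0
    anchor_slack: int = 0
    all_candidates: bool = False
    nn_min_len: int = 14
    na_molar: float = 0.05
    oligo_molar: float = 2.5e-7

    def resolved_window(self) -> int:
        if self.window_size is not None:
            return self.window_size
        return 150 if self.probe else 400

    def validate(self) -> None:
        if self.mode not in ("windowed", "all_oligos"):
            raise ParameterError(f"unknown search mode {self.mode!r}")
        if not 0 < self.oligo_min_len <= self.oligo_max_len:
            raise ParameterError(
                f"oligo length bounds inconsistent: "
                f"[{self.oligo_min_len}, {self.oligo_max_len}]"
            )
        if self.slide < 1:
            raise ParameterError(f"slide must be >= 1, got {self.slide}")
        if self.max_degenerate < 0 or self.clamp_len < 0 or self.anchor_slack < 0:
            raise ParameterError("max_degenerate, clamp_len, anchor_slack must be >= 0")
        if self.td_min > self.td_max:
            raise ParameterError(f"empty Td band [{self.td_min}, {self.td_max}]")
        if not 0.0 <= self.min_conservation <= 1.0:
            raise ParameterError("min_conservation must be in [0, 1]")
        if self.mode == "windowed" and self.oligo_max_len >= self.resolved_window():
            raise ParameterError(
                f"oligo_max_len {self.oligo_max_len} must be smaller than the "
                f"window size {self.resolved_window()}"
            )


@dataclass(frozen=True)
class Oligo:
    """A candidate primer or probe on the consensus.

    start/end are the 0-based half-open binding-site coordinates on the
    consensus; seq is 5'->3' (the reverse complement of the binding site
    for reverse-strand oligos).
    """

    seq: str
    start: int
    end: int
    strand: str  # "fwd" | "rev"
    role: str  # forward_primer | reverse_primer | probe | generic
    degenerate_count: int
    degeneracy: int
    thermo: ThermoSummary

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerSet:
    """Forward + reverse primers (optional probe) and the amplicon they delimit."""

    forward: Oligo
    reverse: Oligo
    probe: Oligo | None
    product_start: int
    product_end: int
    product_seq: str

    @property
    def product_len(self) -> int:
        return self.product_end - self.product_start


def validate_oligo(
    seq: str,
    positions: Sequence[ConsensusPosition],
    params: SearchParams,
    is_probe: bool = False,
) -> tuple[bool, list[str]]:
    """Apply every oligo-validity rule; return (valid, failed-rule ids).

    ``seq`` must already be oriented 5'->3'; ``positions`` is the consensus
    slice it binds.  Validation never raises on sequence content.
    """
    reasons: list[str] = []
    n = len(seq)
    if not params.oligo_min_len <= n <= params.oligo_max_len:
        reasons.append("length")
    if degenerate_count(seq) > params.max_degenerate:
        reasons.append("max_degenerate")
    clamp = 0 if (is_probe and params.probe_no_clamp) else params.clamp_len
    if clamp and degenerate_count(seq[-min(clamp, n) :]) > 0:
        reasons.append("three_prime_clamp")
    lo, hi = td_range(seq)
    if hi < params.td_min or lo > params.td_max:
        reasons.append("td_band")
    if not params.allow_gap_columns and any(p.has_gap for p in positions):
        reasons.append("gap_column")
    if params.min_conservation > 0 and any(
        p.conservation < params.min_conservation for p in positions
    ):
        reasons.append("min_conservation")
    return (not reasons, reasons)


def _oriented(cons: ConsensusSequence, start: int, end: int, strand: str) -> str:
    s = cons.sequence[start:end]
    return s if strand == FORWARD else reverse_complement(s)


def make_oligo(
    cons: ConsensusSequence,
    start: int,
    end: int,
    strand: str,
    role: str,
    params: SearchParams,
) -> Oligo:
    """Build an Oligo (with thermodynamic summary) from consensus coordinates."""
    seq = _oriented(cons, start, end, strand)
    modal = cons.modal_string(start, end)
    if strand == REVERSE:
        modal = reverse_complement(modal)
    thermo = summarize(
        seq,
        modal_seq=modal,
        nn_min_len=params.nn_min_len,
        na_molar=params.na_molar,
        oligo_molar=params.oligo_molar,
    )
    return Oligo(
        seq=seq,
        start=start,
        end=end,
        strand=strand,
        role=role,
        degenerate_count=degenerate_count(seq),
        degeneracy=degeneracy(seq),
        thermo=thermo,
    )


def _valid_candidate(
    cons: ConsensusSequence,
    start: int,
    end: int,
    strand: str,
    role: str,
    params: SearchParams,
    is_probe: bool = False,
) -> Oligo | None:
    seq = _oriented(cons, start, end, strand)
    ok, _ = validate_oligo(seq, cons.slice(start, end), params, is_probe=is_probe)
    return make_oligo(cons, start, end, strand, role, params) if ok else None


def score_candidate(oligo: Oligo, params: SearchParams):
    """Deterministic total preference order for candidates of one role.

    Fewer degenerate positions first; then Td-range midpoint closest to the
    center of the requested band; then longer oligos; then smaller start;
    the strand breaks any remaining tie.  Smaller tuples are better.
    """
    band_center = (params.td_min + params.td_max) / 2.0
    mid = (oligo.thermo.td_min + oligo.thermo.td_max) / 2.0
    return (
        oligo.degenerate_count,
        abs(mid - band_center),
        -oligo.length,
        oligo.start,
        _STRAND_ORDER[oligo.strand],
    )


def enumerate_oligos(cons: ConsensusSequence, params: SearchParams) -> list[Oligo]:
    """List every valid oligo on the consensus (both strands), sorted by
    (start, length, strand).  The all-oligos option for manual design."""
    params.validate()
    length = len(cons)
    if length < params.oligo_min_len:
        log.warning(
            "consensus (%d nt) shorter than the minimum oligo length (%d); "
            "no oligos possible",
            length,
            params.oligo_min_len,
        )
        return []
    out: list[Oligo] = []
    for start in range(length):
        for olen in range(params.oligo_min_len, params.oligo_max_len + 1):
            end = start + olen
            if end > length:
                break
            for strand in (FORWARD, REVERSE):
                cand = _valid_candidate(cons, start, end, strand, "generic", params)
                if cand is not None:
                    out.append(cand)
    out.sort(key=lambda o: (o.start, o.length, _STRAND_ORDER[o.strand]))
    return out


def _forward_candidates(cons, w, params) -> list[Oligo]:
    cands = []
    w_end = w + params.resolved_window()
    for start in range(w, w + params.anchor_slack + 1):
        for olen in range(params.oligo_min_len, params.oligo_max_len + 1):
            end = start + olen
            if end > w_end:
                break
            c = _valid_candidate(cons, start, end, FORWARD, "forward_primer", params)
            if c is not None:
                cands.append(c)
    return cands


def _reverse_candidates(cons, w, params) -> list[Oligo]:
    cands = []
    w_end = w + params.resolved_window()
    for end in range(w_end, w_end - params.anchor_slack - 1, -1):
        for olen in range(params.oligo_min_len, params.oligo_max_len + 1):
            start = end - olen
            if start < w:
                break
            c = _valid_candidate(cons, start, end, REVERSE, "reverse_primer", params)
            if c is not None:
                cands.append(c)
    return cands


def _probe_candidates(cons, lo, hi, params) -> list[Oligo]:
    """Valid probes binding within [lo, hi) (between the primers)."""
    strands = (FORWARD, REVERSE) if params.probe_both_strands else (FORWARD,)
    cands = []
    for start in range(lo, hi):
        for olen in range(params.oligo_min_len, params.oligo_max_len + 1):
            end = start + olen
            if end > hi:
                break
            for strand in strands:
                c = _valid_candidate(
                    cons, start, end, strand, "probe", params, is_probe=True
                )
                if c is not None:
                    cands.append(c)
    return cands


def find_primer_sets(cons: ConsensusSequence, params: SearchParams) -> list[PrimerSet]:
    """Windowed primer(/probe) search.

    One window per start in {0, slide, 2*slide, ...}; windows without a
    complete set are dropped; identical sets found in overlapping windows are
    reported once.  By default the single best-scoring candidate per role is
    kept; with ``all_candidates`` every valid combination is emitted.
    """
    params.validate()
    w_size = params.resolved_window()
    if w_size > len(cons):
        raise ParameterError(
            f"window size {w_size} exceeds consensus length {len(cons)}"
        )
    results: list[PrimerSet] = []
    seen: set[tuple] = set()
    for w in range(0, len(cons) - w_size + 1, params.slide):
        fwd = sorted(_forward_candidates(cons, w, params),
                     key=lambda o: score_candidate(o, params))
        rev = sorted(_reverse_candidates(cons, w, params),
                     key=lambda o: score_candidate(o, params))
        if not fwd or not rev:
            continue
        pairs = (
            itertools.product(fwd, rev) if params.all_candidates else [(fwd[0], rev[0])]
        )
        for f, r in pairs:
            if f.end > r.start:
                continue  # primers may not overlap
            probes: list[Oligo | None]
            if params.probe:
                cand = sorted(
                    _probe_candidates(cons, f.end, r.start, params),
                    key=lambda o: score_candidate(o, params),
                )
                if not cand:
                    continue
                probes = list(cand) if params.all_candidates else [cand[0]]
            else:
                probes = [None]
            for p in probes:
                key = (
                    f.start, f.end, r.start, r.end,
                    None if p is None else (p.start, p.end, p.strand),
                )
                if key in seen:
                    continue
                seen.add(key)
                results.append(
                    PrimerSet(
                        forward=f,
                        reverse=r,
                        probe=p,
                        product_start=f.start,
                        product_end=r.end,
                        product_seq=cons.sequence[f.start : r.end],
                    )
                )
    results.sort(
        key=lambda s: (
            s.product_start,
            s.product_end,
            s.forward.end,
            s.reverse.start,
            -1 if s.probe is None else s.probe.start,
        )
    )
    return results
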