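import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consoligo import (
    ParameterError,
    SearchParams,
    build_consensus,
    degeneracy,
    degenerate_count,
    enumerate_oligos,
    find_primer_sets,
    make_alignment,
    reverse_complement,
    score_candidate,
    validate_oligo,
)
from consoligo.search import make_oligo
from tests.conftest import IUPAC_SETS, cons_from_codes

WIDE = dict(td_min=0.0, td_max=200.0)  # disable the Td filter


# ---------------------------------------------------------------- utilities


@pytest.mark.parametrize(
    "seq,count,deg",
    [("ACGT", 0, 1), ("ACGR", 1, 2), ("RYN", 3, 16), ("NRY", 3, 16), ("N", 1, 4)],
)
def test_degenerate_count_and_degeneracy(seq, count, deg):
    assert degenerate_count(seq) == count
    assert degeneracy(seq) == deg


@pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAR", "YTT"), ("N-", None)])
def test_reverse_complement_examples(seq, expected):
    if expected is None:
        with pytest.raises(ValueError):
            reverse_complement(seq)
    else:
        assert reverse_complement(seq) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=0, max_size=40))
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    for a, b in zip(seq, reversed(reverse_complement(seq))):
        # complement base sets map onto each other
        assert {reverse_complement(x) for x in IUPAC_SETS[a]} == set(IUPAC_SETS[b])


# ---------------------------------------------------------------- validation


def _validate(codes, params, is_probe=False):
    cons = cons_from_codes(codes)
    return validate_oligo(codes, cons.slice(0, len(codes)), params, is_probe)


def test_validate_passes_clean_oligo():
    ok, reasons = _validate("ACGTACGTACGTACGTACGT", SearchParams())  # Td 60
    assert ok and reasons == []


def test_validate_rejects_too_many_degenerate_positions():
    ok, reasons = _validate("RRYY" + "ACGTACGTACGTACGT", SearchParams(**WIDE))
    assert not ok and "max_degenerate" in reasons


def test_validate_rejects_degenerate_three_prime_end():
    ok, reasons = _validate("ACGTACGTACGTACGTAAAR", SearchParams(**WIDE))
    assert not ok and reasons == ["three_prime_clamp"]


def test_probe_clamp_can_be_relaxed():
    params = SearchParams(probe_no_clamp=True, **WIDE)
    ok, _ = _validate("ACGTACGTACGTACGTAAAR", params, is_probe=True)
    assert ok
    ok, reasons = _validate("ACGTACGTACGTACGTAAAR", params, is_probe=False)
    assert not ok and "three_prime_clamp" in reasons


def test_validate_rejects_length_and_td_band():
    ok, reasons = _validate("ACGTACGT", SearchParams(**WIDE))
    assert not ok and reasons == ["length"]
    ok, reasons = _validate("A" * 20, SearchParams())  # Td 40 < 50
    assert not ok and "td_band" in reasons


def test_td_band_uses_range_intersection():
    # GGGWWWWWWWWWWWWWWWWW spans Td [46, 46]... use a seq whose range straddles
    seq = "NNN" + "A" * 14 + "GGG"  # td range [46, 52] straddles td_min=50
    ok, reasons = _validate(seq, SearchParams(td_min=50, td_max=65))
    assert "td_band" not in reasons


def test_gap_columns_block_oligos_unless_allowed():
    # gap at column 5, well clear of the 3' clamp
    cons = build_consensus(make_alignment(["ACGT-CGTACGTACGTACGTACGT",
                                           "ACGTACGTACGTACGTACGTACGT"]))
    seq = cons.sequence[:20]
    ok, reasons = validate_oligo(seq, cons.slice(0, 20), SearchParams(**WIDE))
    assert not ok and "gap_column" in reasons
    ok, _ = validate_oligo(
        seq, cons.slice(0, 20), SearchParams(allow_gap_columns=True, **WIDE)
    )
    assert ok


def test_min_conservation_filter():
    cons = build_consensus(
        make_alignment(["ACGTACGTACGTACGTACGA"] + ["ACGTACGTACGTACGTACGT"] * 3)
    )
    seq = cons.sequence
    ok, reasons = validate_oligo(
        seq, cons.slice(0, 20), SearchParams(min_conservation=0.9, max_degenerate=3, **WIDE)
    )
    assert "min_conservation" in reasons


# ---------------------------------------------------------------- enumerate


def test_enumerate_nondegenerate_consensus_counts():
    cons = cons_from_codes("ACGTACGTACGTACGTACGTACGT")  # 24 nt
    params = SearchParams(
        mode="all_oligos", oligo_min_len=18, oligo_max_len=20, clamp_len=3, **WIDE
    )
    oligos = enumerate_oligos(cons, params)
    # lengths 18,19,20 at starts 0..6,0..5,0..4, both strands
    assert len(oligos) == (7 + 6 + 5) * 2
    assert oligos == sorted(
        oligos, key=lambda o: (o.start, o.length, o.strand != "fwd")
    )


def test_enumerate_all_n_consensus_is_empty():
    assert enumerate_oligos(cons_from_codes("N" * 60), SearchParams(mode="all_oligos")) == []


def test_enumerate_planted_island_only():
    # with zero degenerate positions allowed, only the 20-nt island and its
    # sub-oligos within the length bounds can qualify
    island = "ACGTACGTACGTACGTACGT"  # 20 nt at offset 30
    cons = cons_from_codes("N" * 30 + island + "N" * 30)
    params = SearchParams(mode="all_oligos", max_degenerate=0, **WIDE)
    oligos = enumerate_oligos(cons, params)
    assert oligos, "island must be found"
    for o in oligos:
        assert 30 <= o.start and o.end <= 50
    # lengths 18..20 fitting in a 20-nt island, both strands
    assert len(oligos) == (3 + 2 + 1) * 2
    # at the default cap of 3 degenerate positions, every extra hit can only
    # reach 3 positions into the flanking N runs and must overlap the island
    relaxed = enumerate_oligos(cons, SearchParams(mode="all_oligos", **WIDE))
    assert set(oligos) <= set(relaxed)
    for o in relaxed:
        assert o.degenerate_count <= 3
        assert o.start >= 27 and o.end <= 53


def test_enumerate_short_consensus_warns_and_returns_empty(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="consoligo.search"):
        out = enumerate_oligos(cons_from_codes("ACGT"), SearchParams(mode="all_oligos"))
    assert out == []
    assert any("shorter" in r.message for r in caplog.records)


def brute_force_scan(cons, params):
    """Independent oracle: literal rule application to every substring."""
    sets = IUPAC_SETS
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
            "N": "N"}
    found = []
    codes = cons.sequence
    for start in range(len(codes)):
        for end in range(start + params.oligo_min_len, start + params.oligo_max_len + 1):
            if end > len(codes):
                continue
            fwd = codes[start:end]
            for strand, seq in (("fwd", fwd), ("rev", "".join(comp[c] for c in reversed(fwd)))):
                ndeg = sum(len(sets[c]) > 1 for c in seq)
                if ndeg > params.max_degenerate:
                    continue
                tail = seq[-params.clamp_len:] if params.clamp_len else ""
                if any(len(sets[c]) > 1 for c in tail):
                    continue
                lo = sum(min(2 if b in "AT" else 4 for b in sets[c]) for c in seq)
                hi = sum(max(2 if b in "AT" else 4 for b in sets[c]) for c in seq)
                if hi < params.td_min or lo > params.td_max:
                    continue
                span = cons.positions[start:end]
                if not params.allow_gap_columns and any(p.has_gap for p in span):
                    continue
                if params.min_conservation > 0 and any(
                    p.conservation < params.min_conservation for p in span
                ):
                    continue
                found.append((start, end, strand, seq))
    found.sort(key=lambda t: (t[0], t[1] - t[0], t[2] != "fwd"))
    return found


def test_enumerate_matches_bruteforce_on_random_consensuses():
    rng = random.Random(7)
    for _ in range(25):
        codes = "".join(
            rng.choice("ACGT") if rng.random() < 0.8 else rng.choice("ACGTRYSWKMBDHVN")
            for _ in range(rng.randint(40, 120))
        )
        cons = cons_from_codes(codes)
        params = SearchParams(
            mode="all_oligos",
            oligo_min_len=rng.randint(12, 18),
            oligo_max_len=rng.randint(18, 25),
            max_degenerate=rng.randint(0, 4),
            clamp_len=rng.randint(0, 4),
            td_min=rng.choice([0, 40, 50]),
            td_max=rng.choice([65, 80, 200]),
        )
        got = [(o.start, o.end, o.strand, o.seq) for o in enumerate_oligos(cons, params)]
        assert got == brute_force_scan(cons, params)


# ---------------------------------------------------------------- windowed


def _two_block_consensus(block="ACGTACGTACGTACGTACGT", interior=60):
    return cons_from_codes(block + "N" * interior + block)


def test_windowed_search_recovers_flanking_blocks():
    cons = _two_block_consensus()
    params = SearchParams(window_size=100, slide=20, **WIDE)
    sets = find_primer_sets(cons, params)
    assert len(sets) == 1
    s = sets[0]
    assert (s.forward.start, s.forward.end) == (0, 20)
    assert (s.reverse.start, s.reverse.end) == (80, 100)
    assert s.reverse.seq == reverse_complement(cons.sequence[80:100])
    assert s.product_len == 100 and s.product_seq == cons.sequence
    assert s.probe is None


def test_probe_mode_fails_without_conserved_interior():
    cons = _two_block_consensus()
    params = SearchParams(window_size=100, slide=20, probe=True, **WIDE)
    assert find_primer_sets(cons, params) == []


def test_probe_mode_finds_interior_probe():
    probe_site = "ACGTACGTACGTACGTAC"  # 18 nt
    block = "ACGTACGTACGTACGTACGT"
    cons = cons_from_codes(block + "N" * 20 + probe_site + "N" * 22 + block)
    params = SearchParams(window_size=100, slide=20, probe=True, **WIDE)
    sets = find_primer_sets(cons, params)
    assert len(sets) == 1
    p = sets[0].probe
    assert p is not None and p.strand == "fwd" and p.role == "probe"
    assert sets[0].forward.end <= p.start and p.end <= sets[0].reverse.start


def test_window_arithmetic_on_fully_conserved_consensus():
    cons = cons_from_codes("ACGT" * 50)  # 200 nt
    sets = find_primer_sets(cons, SearchParams(window_size=150, slide=20, **WIDE))
    assert sorted({s.product_start for s in sets}) == [0, 20, 40]
    for s in sets:
        assert s.product_len == 150
        assert s.forward.start == s.product_start
        assert s.reverse.end == s.product_start + 150


def test_window_larger_than_consensus_is_a_parameter_error():
    with pytest.raises(ParameterError):
        find_primer_sets(cons_from_codes("ACGT" * 25), SearchParams(window_size=150))
    with pytest.raises(ParameterError):
        SearchParams(window_size=20, oligo_max_len=25).validate()


def test_emitted_oligos_repass_validation_and_coordinates():
    cons = _two_block_consensus()
    params = SearchParams(window_size=100, slide=20, **WIDE)
    for s in find_primer_sets(cons, params):
        for o, probe in ((s.forward, False), (s.reverse, False)):
            ok, reasons = validate_oligo(
                o.seq, cons.slice(o.start, o.end), params, is_probe=probe
            )
            assert ok, reasons
            expected = cons.sequence[o.start:o.end]
            if o.strand == "rev":
                expected = reverse_complement(expected)
            assert o.seq == expected


def test_relaxing_constraints_never_shrinks_results():
    rng = random.Random(11)
    codes = "".join(
        rng.choice("ACGT") if rng.random() < 0.7 else rng.choice("RYSWKM")
        for _ in range(150)
    )
    cons = cons_from_codes(codes)
    strict = SearchParams(mode="all_oligos", max_degenerate=1, td_min=50, td_max=60)
    loose = SearchParams(mode="all_oligos", max_degenerate=3, td_min=45, td_max=70)
    key = lambda o: (o.start, o.end, o.strand)
    got_strict = {key(o) for o in enumerate_oligos(cons, strict)}
    got_loose = {key(o) for o in enumerate_oligos(cons, loose)}
    assert got_strict <= got_loose


def test_search_is_deterministic():
    cons = _two_block_consensus()
    params = SearchParams(window_size=100, slide=20, **WIDE)
    assert find_primer_sets(cons, params) == find_primer_sets(cons, params)
    p2 = SearchParams(mode="all_oligos", **WIDE)
    assert enumerate_oligos(cons, p2) == enumerate_oligos(cons, p2)


def test_scoring_prefers_fewer_degenerate_then_td_centering():
    cons = cons_from_codes("ACGTACGTACGTACGTACGTR" + "ACGTACGTACGTACGTACGT")
    params = SearchParams()
    a = make_oligo(cons, 0, 20, "fwd", "generic", params)   # 0 degenerate
    b = make_oligo(cons, 0, 21, "fwd", "generic", params)   # 1 degenerate (R)
    assert score_candidate(a, params) < score_candidate(b, params)
    # equal degeneracy: Td midpoint nearer the band center wins
    band = SearchParams(td_min=50, td_max=65)  # center 57.5
    mid_57 = make_oligo(cons, 21, 40, "fwd", "generic", band)
    assert abs(sum(td_range(mid_57.seq)) / 2 - 57.5) >= 0  # smoke: total order
    assert score_candidate(a, band) != score_candidate(b, band)


def test_duplicate_sets_across_overlapping_windows_reported_once():
    # conserved blocks at 0-20 and 80-100 inside a 120-nt consensus with
    # window 100: windows at 0 and 20 could both see block pairs; identical
    # (forward, reverse) coordinate pairs must appear once
    cons = cons_from_codes("ACGTACGTACGTACGTACGT" + "N" * 60 + "ACGTACGTACGTACGTACGT" + "N" * 20)
    sets = find_primer_sets(cons, SearchParams(window_size=100, slide=20, **WIDE))
    keys = [(s.forward.start, s.forward.end, s.reverse.start, s.reverse.end) for s in sets]
    assert len(keys) == len(set(keys))


from consoligo import td_range  # noqa: E402  (used in scoring test)
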