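"""Chain selection, connection classification and the four within-scaffold detectors."""

import itertools
import random

import pytest

from txrefine.psl import make_record
from txrefine.txalign import (
    AlignmentSegment,
    classify_connection,
    detect_nested,
    detect_strand_inconsistency,
    find_boundary_extensions,
    find_gap_closures,
    segments_from_record,
    select_optimal_chain,
)


def seg(q0, q1, scaf="s1", g0=None, g1=None, strand="+", matches=None, tid="t"):
    if g0 is None:
        g0 = q0 + 1000
    if g1 is None:
        g1 = g0 + (q1 - q0)
    return AlignmentSegment(tid, q0, q1, scaf, g0, g1, strand, matches or (q1 - q0))


# -- segment construction ----------------------------------------------------

def test_query_gap_splits_segments_intron_does_not():
    # blocks q-contiguous across a target jump merge into one segment ...
    rec = make_record("t", 400, "s1", 9000, "+", [(0, 1000), (150, 3000)], [150, 150])
    segs = segments_from_record(rec)
    assert len(segs) == 1
    assert (segs[0].q_start, segs[0].q_end) == (0, 300)
    assert (segs[0].g_start, segs[0].g_end) == (1000, 3150)
    assert segs[0].block_gap_bases == 3150 - 1000 - 300
    # ... while a query gap opens a new segment
    rec = make_record("t", 400, "s1", 9000, "+", [(0, 1000), (200, 3000)], [150, 150])
    segs = segments_from_record(rec)
    assert [(s.q_start, s.q_end) for s in segs] == [(0, 150), (200, 350)]


# -- optimal chain -----------------------------------------------------------

def test_chain_argmax_of_two_exclusive_placements():
    a = seg(0, 300, matches=280)
    b = seg(0, 300, g0=4000, matches=150)
    chain = select_optimal_chain([a, b])
    assert chain.segments == [a]


def test_chain_keeps_compatible_segments_and_reports_span():
    a = seg(0, 200)
    b = seg(220, 400)
    chain = select_optimal_chain([a, b], transcript_length=400)
    assert chain.segments == [a, b]
    assert chain.unaligned_spans == [(200, 220)]


def _oracle_best(segs):
    best = (0, 0)  # (score, -count)
    for r in range(len(segs) + 1):
        for combo in itertools.combinations(segs, r):
            ordered = sorted(combo, key=lambda s: s.q_start)
            if any(b.q_start < a.q_end for a, b in zip(ordered, ordered[1:])):
                continue
            cand = (sum(s.matches for s in combo), -len(combo))
            best = max(best, cand)
    return best


def test_chain_equals_exhaustive_search_on_random_instances():
    rng = random.Random(20240915)
    for _ in range(100):
        n = rng.randint(1, 10)
        segs = []
        for _i in range(n):
            q0 = rng.randrange(0, 900)
            q1 = q0 + rng.randint(20, 200)
            m = rng.randint(1, q1 - q0)
            segs.append(seg(q0, q1, g0=rng.randrange(0, 100000), matches=m))
        chain = select_optimal_chain(segs, transcript_length=1200)
        got = (sum(s.matches for s in chain.segments), -len(chain.segments))
        assert got == _oracle_best(segs)
        # chosen segments must be q-compatible and spans must tile the rest
        for a, b in zip(chain.segments, chain.segments[1:]):
            assert a.q_end <= b.q_start
        covered = sum(s.q_end - s.q_start for s in chain.segments)
        gaps = sum(e - s for s, e in chain.unaligned_spans)
        assert covered + gaps == 1200


def test_chain_requires_segments():
    with pytest.raises(ValueError):
        select_optimal_chain([])


# -- connection classification -----------------------------------------------

LENGTHS = {"A": 6000, "B": 6000, "C": 500}


def chain_of(*segs):
    return select_optimal_chain(list(segs))


def test_ok_join_terminal_adjacency_plus():
    c = chain_of(
        seg(0, 300, "A", 5700, 6000),        # ends at A's end
        seg(300, 600, "B", 0, 300),          # starts at B's start
    )
    call = classify_connection(c, LENGTHS, {})
    assert call.connection_class == "OK_join"
    assert call.scaffolds == ("A", "B")
    assert call.pattern_bucket == "++"


def test_ok_join_minus_strand():
    c = chain_of(
        seg(0, 300, "A", 0, 300, strand="-"),
        seg(300, 600, "B", 5700, 6000, strand="-"),
    )
    assert classify_connection(c, LENGTHS, {}).connection_class == "OK_join"


def test_join_outside_edge_tol_is_pb_merge():
    c = chain_of(
        seg(0, 300, "A", 5000, 5300),  # 700 bp from A's end > edge_tol
        seg(300, 600, "B", 0, 300),
    )
    assert classify_connection(c, LENGTHS, {}).connection_class == "PB_merge"


def test_ok_merge_sandwich_over_n_run():
    gap_map = {"A": [(3000, 3400)]}  # 400-N run hosts C's 300-bp span
    c = chain_of(
        seg(0, 300, "A", 2700, 3000),
        seg(300, 600, "C", 100, 400),
        seg(600, 900, "A", 3400, 3700),
    )
    call = classify_connection(c, LENGTHS, gap_map)
    assert call.connection_class == "OK_merge"
    assert call.scaffolds == ("A", "C")


def test_merge_needs_gap_at_least_insert_span():
    gap_map = {"A": [(3000, 3200)]}  # 200-N run too small for 300-bp insert
    c = chain_of(
        seg(0, 300, "A", 2700, 3000),
        seg(300, 600, "C", 100, 400),
        seg(600, 900, "A", 3200, 3500),
    )
    assert classify_connection(c, LENGTHS, gap_map).connection_class == "PB_merge"


def test_mixed_strand_cross_scaffold_is_pb_merge():
    c = chain_of(
        seg(0, 300, "A", 5700, 6000, strand="+"),
        seg(300, 600, "B", 0, 300, strand="-"),
    )
    call = classify_connection(c, LENGTHS, {})
    assert call.connection_class == "PB_merge"
    assert call.pattern_bucket == "+-/-+"


def test_single_scaffold_chain_rejected():
    with pytest.raises(ValueError):
        classify_connection(chain_of(seg(0, 300)), LENGTHS, {})


# -- strand inconsistency ----------------------------------------------------

def test_ascending_plus_plus_silent():
    c = chain_of(seg(0, 200, g0=1000), seg(200, 400, g0=2000))
    assert detect_strand_inconsistency(c) == []


def test_descending_minus_minus_silent():
    c = chain_of(
        seg(0, 200, g0=2000, strand="-"), seg(200, 400, g0=1000, strand="-")
    )
    assert detect_strand_inconsistency(c) == []


def test_ascending_plus_minus_flagged():
    c = chain_of(seg(0, 200, g0=1000), seg(200, 400, g0=2000, strand="-"))
    calls = detect_strand_inconsistency(c)
    assert len(calls) == 1 and calls[0].orientation_pattern == "+-"


def test_descending_plus_plus_flagged():
    c = chain_of(seg(0, 200, g0=2000), seg(200, 400, g0=1000))
    assert len(detect_strand_inconsistency(c)) == 1


# -- nests --------------------------------------------------------------------

def test_nest_overlap_200():
    c = chain_of(seg(0, 400, g0=1000, g1=1400), seg(400, 800, g0=1200, g1=1600))
    calls = detect_nested(c)
    assert len(calls) == 1 and calls[0].details["overlap"] == 200
    assert not calls[0].details["containment"]


def test_nest_containment_noted():
    c = chain_of(seg(0, 400, g0=1000, g1=1400), seg(400, 500, g0=1100, g1=1200))
    calls = detect_nested(c)
    assert len(calls) == 1 and calls[0].details["containment"]


def test_disjoint_ascending_no_nest():
    c = chain_of(seg(0, 400, g0=1000), seg(400, 800, g0=1500))
    assert detect_nested(c) == []


def test_overlap_below_threshold_ignored():
    c = chain_of(seg(0, 400, g0=1000, g1=1400), seg(400, 800, g0=1390, g1=1800))
    assert detect_nested(c, nest_min_overlap=20) == []
    assert len(detect_nested(c, nest_min_overlap=10)) == 1


# -- boundary extensions -------------------------------------------------------

def test_tail_extension_at_scaffold_end():
    c = select_optimal_chain([seg(0, 280, "A", 5720, 6000)], transcript_length=400)
    calls = find_boundary_extensions(c, LENGTHS, transcript_seq="G" * 400)
    assert len(calls) == 1
    call = calls[0]
    assert call.details == {"side": "right", "length": 120}
    assert call.coordinates == (6000,) and call.payload == "G" * 120


def test_far_from_scaffold_end_no_call():
    c = select_optimal_chain([seg(0, 280, "A", 500, 780)], transcript_length=400)
    assert find_boundary_extensions(c, LENGTHS) == []


def test_extensions_at_both_ends_two_scaffolds():
    # on '+', an upstream unaligned span extends past the segment's g_start,
    # so the first segment must sit at A's head and the last at B's tail
    c = select_optimal_chain(
        [seg(100, 300, "A", 0, 200), seg(300, 500, "B", 5800, 6000)],
        transcript_length=600,
    )
    calls = find_boundary_extensions(c, LENGTHS, transcript_seq="A" * 600)
    assert {(c.scaffolds[0], c.details["side"]) for c in calls} == {
        ("A", "left"), ("B", "right"),
    }


def test_minus_strand_extension_payload_revcomped():
    # upstream unaligned span + '-' segment extends the right scaffold end
    c = select_optimal_chain(
        [seg(100, 300, "A", 5800, 6000, strand="-")], transcript_length=300
    )
    txseq = "A" * 100 + "C" * 200
    calls = find_boundary_extensions(c, LENGTHS, transcript_seq=txseq)
    assert len(calls) == 1
    assert calls[0].details["side"] == "right"
    assert calls[0].payload == "T" * 100


# -- gap closures ---------------------------------------------------------------

def test_exact_gap_fill():
    gap_map = {"A": [(1200, 1300)]}
    c = select_optimal_chain(
        [seg(0, 200, "A", 1000, 1200), seg(300, 500, "A", 1300, 1500)],
        transcript_length=500,
    )
    calls = find_gap_closures(c, gap_map, transcript_seq="T" * 500)
    assert len(calls) == 1
    d = calls[0].details
    assert d == {"filled_length": 100, "predicted_gap_length": 100, "exact_match": True}
    assert calls[0].coordinates == (1200, 1300)


def test_inexact_gap_fill():
    gap_map = {"A": [(1200, 1300)]}
    c = select_optimal_chain(
        [seg(0, 200, "A", 1000, 1200), seg(340, 500, "A", 1300, 1460)],
        transcript_length=500,
    )
    calls = find_gap_closures(c, gap_map)
    assert len(calls) == 1 and not calls[0].details["exact_match"]
    assert calls[0].details["filled_length"] == 140


def test_no_n_run_no_call():
    c = select_optimal_chain(
        [seg(0, 200, "A", 1000, 1200), seg(300, 500, "A", 1300, 1500)],
        transcript_length=500,
    )
    assert find_gap_closures(c, {}) == []


def test_minus_strand_gap_fill_payload_revcomped():
    gap_map = {"A": [(1200, 1250)]}
    c = select_optimal_chain(
        [
            seg(0, 200, "A", 1250, 1450, strand="-"),
            seg(250, 450, "A", 1000, 1200, strand="-"),
        ],
        transcript_length=450,
    )
    txseq = "A" * 200 + "C" * 50 + "A" * 200
    calls = find_gap_closures(c, gap_map, transcript_seq=txseq)
    assert len(calls) == 1 and calls[0].payload == "G" * 50
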