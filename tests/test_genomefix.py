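"""Gap map, genome editing and assembly statistics."""

import random
import re

import pytest

from txrefine.genomefix import (
    EditConflictError,
    apply_improvements,
    assembly_stats,
    build_gap_map,
    contig_lengths,
    nxx,
)
from txrefine.txalign import ImprovementCall


def fill_call(scaf, gs, ge, payload, tid="t"):
    return ImprovementCall(
        kind="gap_fill", transcript_id=tid, scaffolds=(scaf,),
        coordinates=(gs, ge), orientation_pattern="++", payload=payload,
        details={"filled_length": len(payload), "predicted_gap_length": ge - gs,
                 "exact_match": len(payload) == ge - gs},
    )


def ext_call(scaf, side, payload, anchor=0, tid="t"):
    return ImprovementCall(
        kind="boundary_extension", transcript_id=tid, scaffolds=(scaf,),
        coordinates=(anchor,), orientation_pattern="+", payload=payload,
        details={"side": side, "length": len(payload)},
    )


# -- gap map --------------------------------------------------------------------

def test_gap_map_simple():
    gaps = build_gap_map({"s": "ACGT" + "N" * 10 + "ACGT"})["s"]
    assert [(g.start, g.end) for g in gaps] == [(4, 14)]
    assert gaps[0].predicted_length == 10


def test_gap_map_no_ns():
    assert build_gap_map({"s": "ACGTACGT"}) == {}


def test_short_runs_below_min_ignored():
    seq = "ACGT" + "N" * 9 + "ACGT" + "N" * 10 + "ACGT"
    gaps = build_gap_map({"s": seq})["s"]
    assert [(g.start, g.end) for g in gaps] == [(17, 27)]


def test_gap_map_matches_regex_oracle():
    rng = random.Random(77)
    for _ in range(20):
        parts = []
        for _i in range(7):
            parts.append("".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60))))
            parts.append("N" * rng.randint(1, 40))
        seq = "".join(parts) + "ACGT"
        want = [
            (m.start(), m.end())
            for m in re.finditer(r"N{10,}", seq)
        ]
        got = [(g.start, g.end) for g in build_gap_map({"s": seq}).get("s", [])]
        assert got == want


# -- editing ----------------------------------------------------------------------

def test_exact_fill_preserves_length_and_removes_ns():
    genome = {"s": "A" * 500 + "N" * 100 + "C" * 500}
    out, log = apply_improvements(genome, [fill_call("s", 500, 600, "G" * 100)])
    assert len(out["s"]) == 1100 and "N" not in out["s"]
    assert out["s"][:500] == "A" * 500 and out["s"][600:] == "C" * 500
    assert log[0]["action"] == "gap_fill" and log[0]["length_change"] == 0


def test_inexact_fill_shifts_downstream():
    genome = {"s": "A" * 500 + "N" * 100 + "C" * 500}
    out, _ = apply_improvements(genome, [fill_call("s", 500, 600, "G" * 140)])
    assert len(out["s"]) == 1140
    assert out["s"][500:640] == "G" * 140 and out["s"][640:] == "C" * 500


def test_two_fills_same_scaffold_shift_bookkeeping():
    genome = {"s": "A" * 100 + "N" * 50 + "C" * 100 + "N" * 50 + "T" * 100}
    calls = [
        fill_call("s", 250, 300, "G" * 80),  # applied in coordinate order
        fill_call("s", 100, 150, "G" * 30),
    ]
    out, log = apply_improvements(genome, calls)
    assert out["s"] == "A" * 100 + "G" * 30 + "C" * 100 + "G" * 80 + "T" * 100
    assert [e["old_start"] for e in log] == [100, 250]


def test_extension_adds_at_end():
    genome = {"s": "A" * 100}
    out, _ = apply_improvements(
        genome, [ext_call("s", "right", "G" * 120, anchor=100)]
    )
    assert out["s"] == "A" * 100 + "G" * 120


def test_extension_adds_at_start():
    genome = {"s": "A" * 100}
    out, _ = apply_improvements(genome, [ext_call("s", "left", "G" * 30)])
    assert out["s"] == "G" * 30 + "A" * 100


def test_overlapping_fills_conflict():
    genome = {"s": "A" * 100 + "N" * 100 + "C" * 100}
    calls = [
        fill_call("s", 100, 160, "G" * 60, tid="t1"),
        fill_call("s", 150, 200, "G" * 50, tid="t2"),
    ]
    with pytest.raises(EditConflictError):
        apply_improvements(genome, calls)


def test_duplicate_side_extensions_conflict():
    genome = {"s": "A" * 100}
    calls = [
        ext_call("s", "right", "G" * 10, anchor=100, tid="t1"),
        ext_call("s", "right", "C" * 10, anchor=100, tid="t2"),
    ]
    with pytest.raises(EditConflictError):
        apply_improvements(genome, calls)


def test_identical_duplicate_calls_collapse():
    genome = {"s": "A" * 100 + "N" * 50 + "C" * 100}
    call = fill_call("s", 100, 150, "G" * 50)
    out, log = apply_improvements(genome, [call, call])
    assert len(log) == 1 and out["s"].count("G") == 50


def test_fill_must_target_n_run():
    genome = {"s": "A" * 300}
    with pytest.raises(EditConflictError):
        apply_improvements(genome, [fill_call("s", 100, 150, "G" * 50)])


def test_join_policy():
    genome = {"a": "A" * 100, "b": "C" * 100}
    join = ImprovementCall(
        kind="join", transcript_id="t", scaffolds=("a", "b"),
        coordinates=(100, 0), orientation_pattern="++",
    )
    out, log = apply_improvements(genome, [join], policy="with-joins")
    assert set(out) == {"a|b"}
    assert out["a|b"] == "A" * 100 + "N" * 100 + "C" * 100
    # conservative leaves joins unapplied
    out2, log2 = apply_improvements(genome, [join])
    assert out2 == genome and log2 == []


def test_unknown_policy_rejected():
    with pytest.raises(ValueError):
        apply_improvements({}, [], policy="aggressive")


# -- statistics --------------------------------------------------------------------

def test_n50_worked_example():
    assert nxx([40, 30, 20, 10], 0.50) == 30
    assert nxx([40, 30, 20, 10], 0.90) == 20  # 40+30+20 = 90 >= 90


def test_single_contig():
    assert nxx([1000], 0.50) == 1000
    assert nxx([1000], 0.90) == 1000


def test_nxx_empty():
    assert nxx([], 0.5) == 0


def _oracle_nxx(lengths, fraction):
    total = sum(lengths)
    best = 0
    for L in set(lengths):
        if sum(x for x in lengths if x >= L) >= fraction * total:
            best = max(best, L)
    return best


def test_nxx_matches_bruteforce_on_random_multisets():
    rng = random.Random(4242)
    for _ in range(100):
        lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 40))]
        for frac in (0.5, 0.9):
            assert nxx(lengths, frac) == _oracle_nxx(lengths, frac)


def test_contig_lengths_split_at_gaps():
    genome = {"s": "A" * 40 + "N" * 12 + "C" * 30, "u": "G" * 25}
    assert sorted(contig_lengths(genome)) == [25, 30, 40]


def test_exact_fills_reduce_contig_count_keep_scaffold_length(fx, improvement):
    before, after = improvement.stats_before, improvement.stats_after
    n_fills = len(improvement.scan.calls_of_kind("gap_fill"))
    n_exts = len(improvement.scan.calls_of_kind("boundary_extension"))
    assert n_fills > 0 and n_exts > 0
    # one contiguous contig replaces two flanks per filled gap
    assert after.contig_count == before.contig_count - n_fills
    ext_bp = sum(
        c.details["length"] for c in improvement.scan.calls_of_kind("boundary_extension")
    )
    fill_shift = sum(
        c.details["filled_length"] - c.details["predicted_gap_length"]
        for c in improvement.scan.calls_of_kind("gap_fill")
    )
    assert after.total_bases == before.total_bases + ext_bp + fill_shift
    assert after.contig_n50 >= before.contig_n50


def test_edited_genome_is_byte_identical_outside_edits(fx, improvement):
    edited = {e["scaffold"] for e in improvement.edit_log}
    for sid, seq in fx.draft_genome.items():
        if sid not in edited:
            assert improvement.improved_genome[sid] == seq
    # per-scaffold spot check using the log's new coordinates
    for e in improvement.edit_log:
        new = improvement.improved_genome[e["scaffold"]]
        if e["action"] == "gap_fill":
            assert "N" not in new[e["new_start"]: e["new_end"]]
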