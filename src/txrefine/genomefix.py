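"""Apply accepted improvement calls to a draft genome; assembly statistics.

Edits are conservative by default: gap closures replace N-runs with
transcript-derived sequence and boundary extensions append sequence at
scaffold ends. Scaffold joins are emitted by the scanner but applied only
under the ``with-joins`` policy, using a fixed-length N spacer flagged as
unknown-length, because transcript evidence cannot estimate the gap between
scaffolds (intron lengths are unknown). Mis-assembly reports (PB_merge,
strand inconsistencies, nests) are never auto-edited.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .txalign import ImprovementCall

__all__ = [
    "GapRecord",
    "AssemblyStats",
    "EditConflictError",
    "build_gap_map",
    "gap_map_as_tuples",
    "apply_improvements",
    "assembly_stats",
    "contig_lengths",
    "nxx",
]

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class GapRecord:
    scaffold_id: str
    start: int
    end: int  # 0-based half-open

    @property
    def predicted_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyStats:
    contig_count: int
    contig_n50: int
    contig_n90: int
    scaffold_count: int
    total_bases: int
    total_gap_bases: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class EditConflictError(ValueError):
    """Two accepted edits target overlapping intervals of one scaffold."""


def build_gap_map(
    genome: Mapping[str, str], min_gap_len: int = 10
) -> dict[str, list[GapRecord]]:
    """Locate maximal N-runs of length >= min_gap_len per scaffold, sorted."""
    gaps: dict[str, list[GapRecord]] = {}
    for sid in sorted(genome):
        runs = [
            GapRecord(sid, m.start(), m.end())
            for m in _N_RUN.finditer(genome[sid])
            if m.end() - m.start() >= min_gap_len
        ]
        if runs:
            gaps[sid] = runs
    return gaps


def gap_map_as_tuples(
    gap_map: Mapping[str, Sequence[GapRecord]],
) -> dict[str, list[tuple[int, int]]]:
    """Plain (start, end) view of a gap map, as the scanner consumes it."""
    return {sid: [(g.start, g.end) for g in recs] for sid, recs in gap_map.items()}


def _dedupe(calls: Iterable[ImprovementCall]) -> list[ImprovementCall]:
    seen = set()
    out = []
    for c in calls:
        key = (c.kind, c.scaffolds, c.coordinates,
               c.details.get("side"), c.payload)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


def apply_improvements(
    genome: Mapping[str, str],
    calls: Sequence[ImprovementCall],
    policy: str = "conservative",
    join_spacer_len: int = 100,
) -> tuple[dict[str, str], list[dict]]:
    """Apply gap fills and boundary extensions (and joins under with-joins).

    Returns the improved genome and an AGP-style edit log; sequence outside
    edited intervals is byte-identical to the input. Overlapping interval
    edits raise EditConflictError; identical duplicate calls (the same edit
    supported by several transcripts) are collapsed to one.
    """
    if policy not in ("conservative", "with-joins"):
        raise ValueError(f"unknown policy {policy!r}")
    calls = _dedupe(calls)
    fills: dict[str, list[ImprovementCall]] = {}
    extensions: dict[str, list[ImprovementCall]] = {}
    joins: list[ImprovementCall] = []
    for c in calls:
        if c.kind == "gap_fill":
            fills.setdefault(c.scaffolds[0], []).append(c)
        elif c.kind == "boundary_extension":
            extensions.setdefault(c.scaffolds[0], []).append(c)
        elif c.kind == "join" and policy == "with-joins":
            joins.append(c)
        # mis_scaffold / strand_inconsistency / nest / merge: report-only

    improved: dict[str, str] = dict(genome)
    log: list[dict] = []

    for sid, scalls in fills.items():
        scalls.sort(key=lambda c: c.coordinates[0])
        for a, b in zip(scalls, scalls[1:]):
            if b.coordinates[0] < a.coordinates[1]:
                raise EditConflictError(
                    f"overlapping gap fills on {sid}: "
                    f"{a.transcript_id}@{a.coordinates} vs "
                    f"{b.transcript_id}@{b.coordinates}"
                )
        seq = improved[sid]
        shift = 0
        for c in scalls:
            gs, ge = c.coordinates
            if set(seq[gs + shift: ge + shift]) != {"N"}:
                raise EditConflictError(
                    f"gap fill on {sid}[{gs},{ge}) does not target an N-run"
                )
            seq = seq[: gs + shift] + c.payload + seq[ge + shift:]
            log.append(
                {
                    "scaffold": sid,
                    "action": "gap_fill",
                    "old_start": gs,
                    "old_end": ge,
                    "new_start": gs + shift,
                    "new_end": gs + shift + len(c.payload),
                    "length_change": len(c.payload) - (ge - gs),
                    "exact_match": c.details.get("exact_match"),
                    "transcript": c.transcript_id,
                }
            )
            shift += len(c.payload) - (ge - gs)
        improved[sid] = seq

    for sid, scalls in extensions.items():
        sides = [c.details.get("side") for c in scalls]
        for side in ("left", "right"):
            if sides.count(side) > 1:
                dup = [c for c in scalls if c.details.get("side") == side]
                raise EditConflictError(
                    f"multiple {side}-end extensions on {sid}: "
                    + ", ".join(c.transcript_id for c in dup)
                )
        seq = improved[sid]
        for c in scalls:
            side = c.details.get("side")
            if side == "right":
                log.append(
                    {
                        "scaffold": sid,
                        "action": "extend_right",
                        "old_start": len(seq),
                        "old_end": len(seq),
                        "new_start": len(seq),
                        "new_end": len(seq) + len(c.payload),
                        "length_change": len(c.payload),
                        "transcript": c.transcript_id,
                    }
                )
                seq = seq + c.payload
            else:
                log.append(
                    {
                        "scaffold": sid,
                        "action": "extend_left",
                        "old_start": 0,
                        "old_end": 0,
                        "new_start": 0,
                        "new_end": len(c.payload),
                        "length_change": len(c.payload),
                        "transcript": c.transcript_id,
                    }
                )
                seq = c.payload + seq
        improved[sid] = seq

    consumed: set[str] = set()
    for c in joins:
        a, b = c.scaffolds[0], c.scaffolds[1]
        if a in consumed or b in consumed:
            raise EditConflictError(f"scaffold reused across joins: {a}, {b}")
        if set(c.orientation_pattern) == {"-"}:
            a, b = b, a  # '-' chains traverse the adjacency in reverse
        joined_id = f"{a}|{b}"
        improved[joined_id] = improved.pop(a) + "N" * join_spacer_len + improved.pop(b)
        consumed.update((a, b))
        log.append(
            {
                "scaffold": joined_id,
                "action": "join",
                "parts": [a, b],
                "spacer": join_spacer_len,
                "gap_length_known": False,
                "transcript": c.transcript_id,
            }
        )

    return improved, log


def contig_lengths(genome: Mapping[str, str], min_gap_len: int = 10) -> list[int]:
    """Lengths of scaffold substrings split at N-runs >= min_gap_len."""
    gap_map = build_gap_map(genome, min_gap_len)
    lengths: list[int] = []
    for sid, seq in genome.items():
        pos = 0
        for gap in gap_map.get(sid, ()):
            if gap.start > pos:
                lengths.append(gap.start - pos)
            pos = gap.end
        if len(seq) > pos:
            lengths.append(len(seq) - pos)
    return lengths


def nxx(lengths: Sequence[int], fraction: float) -> int:
    """Largest L such that contigs of length >= L hold >= fraction of bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= fraction * total:
            return length
    return min(lengths)


def assembly_stats(genome: Mapping[str, str], min_gap_len: int = 10) -> AssemblyStats:
    lengths = contig_lengths(genome, min_gap_len)
    gap_map = build_gap_map(genome, min_gap_len)
    total_gaps = sum(g.predicted_length for recs in gap_map.values() for g in recs)
    return AssemblyStats(
        contig_count=len(lengths),
        contig_n50=nxx(lengths, 0.50),
        contig_n90=nxx(lengths, 0.90),
        scaffold_count=len(genome),
        total_bases=sum(len(s) for s in genome.values()),
        total_gap_bases=total_gaps,
    )
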