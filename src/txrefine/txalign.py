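"""Interpretation of transcript-to-genome split alignments.

Assembled transcripts aligned back to a fragmented draft genome carry
structural evidence about the assembly itself. A transcript whose ordered
segments land on two scaffold ends supports joining them; one whose middle
segment lands on a second scaffold the size of an N-run gap supports merging
that scaffold into the gap; order/strand patterns other than ascending "++"
or descending "--" flag mis-assembly; overlapping genome footprints of
consecutive segments flag a collapsed repeat (nest); unaligned transcript
ends or interiors abutting scaffold boundaries or N-runs supply boundary
extensions and gap closures.

The module parses PSL alignments into segments, selects each transcript's
optimal chain (maximum matched bases over non-overlapping transcript
intervals), classifies multi-scaffold chains into the three connection
classes (OK_join / OK_merge / PB_merge), and emits typed improvement calls.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .psl import PslRecord, read_psl

__all__ = [
    "AlignmentSegment",
    "TranscriptChain",
    "ImprovementCall",
    "ConnectionCall",
    "parse_psl",
    "segments_from_record",
    "select_optimal_chain",
    "classify_connection",
    "detect_strand_inconsistency",
    "detect_nested",
    "find_boundary_extensions",
    "find_gap_closures",
    "scan_alignments",
    "ScanResult",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentSegment:
    """One contiguous aligned stretch of a transcript on the genome.

    Transcript (q) coordinates are forward-strand 0-based half-open; genome
    (g) coordinates are forward 0-based half-open regardless of strand.
    """

    transcript_id: str
    q_start: int
    q_end: int
    scaffold_id: str
    g_start: int
    g_end: int
    strand: str
    matches: int
    block_gap_bases: int = 0

    def __post_init__(self) -> None:
        assert self.q_start < self.q_end and self.g_start < self.g_end
        assert self.strand in "+-"


@dataclass
class TranscriptChain:
    transcript_id: str
    transcript_length: int
    segments: list[AlignmentSegment]  # ordered by q_start
    unaligned_spans: list[tuple[int, int]]

    @property
    def scaffolds(self) -> list[str]:
        return [s.scaffold_id for s in self.segments]

    @property
    def orientation_pattern(self) -> str:
        return "".join(s.strand for s in self.segments)

    def is_multi_scaffold(self) -> bool:
        return len(set(self.scaffolds)) > 1


@dataclass
class ImprovementCall:
    kind: str  # join | merge | mis_scaffold | strand_inconsistency | nest |
    #            boundary_extension | gap_fill
    transcript_id: str
    scaffolds: tuple[str, ...]
    coordinates: tuple[int, ...]
    orientation_pattern: str
    payload: str | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        needs_payload = self.kind in ("boundary_extension", "gap_fill")
        assert (self.payload is not None) == needs_payload, self.kind


@dataclass
class ConnectionCall:
    connection_class: str  # OK_join | OK_merge | PB_merge
    scaffolds: tuple[str, ...]
    supporting_transcripts: tuple[str, ...]
    orientation_pattern: str

    @property
    def pattern_bucket(self) -> str:
        """Table-style strand bucket: '++', '--' or '+-/-+'."""
        strands = set(self.orientation_pattern)
        if strands == {"+"}:
            return "++"
        if strands == {"-"}:
            return "--"
        return "+-/-+"


def segments_from_record(rec: PslRecord) -> list[AlignmentSegment]:
    """Split one PSL record into segments at transcript-coordinate gaps.

    Blocks contiguous in query are merged into one segment even when the
    target jumps (introns); a query gap opens a new segment, since an
    unaligned transcript span is structural evidence downstream.
    """
    blocks = list(zip(rec.block_sizes, rec.q_starts, rec.t_starts))
    segments: list[AlignmentSegment] = []
    cur: list[tuple[int, int, int]] = []

    def flush() -> None:
        if not cur:
            return
        if rec.strand == "+":
            q_lo = cur[0][1]
            q_hi = cur[-1][1] + cur[-1][0]
        else:
            # native q coords are reversed: convert extremes
            q_hi = rec.q_size - cur[0][1]
            q_lo = rec.q_size - (cur[-1][1] + cur[-1][0])
        g_lo = min(t for _, _, t in cur)
        g_hi = max(t + bs for bs, _, t in cur)
        total = sum(bs for bs, _, _ in cur)
        segments.append(
            AlignmentSegment(
                transcript_id=rec.q_name,
                q_start=q_lo,
                q_end=q_hi,
                scaffold_id=rec.t_name,
                g_start=g_lo,
                g_end=g_hi,
                strand=rec.strand,
                matches=total,
                block_gap_bases=(g_hi - g_lo) - total,
            )
        )

    for bs, qs, ts in blocks:
        if cur and qs != cur[-1][1] + cur[-1][0]:  # query gap -> new segment
            flush()
            cur = []
        cur.append((bs, qs, ts))
    flush()
    return segments


def parse_psl(path) -> list[AlignmentSegment]:
    """Read a PSL file into alignment segments (query-forward coordinates)."""
    segments: list[AlignmentSegment] = []
    for rec in read_psl(path):
        segments.extend(segments_from_record(rec))
    return segments


def select_optimal_chain(
    segments: Sequence[AlignmentSegment], transcript_length: int | None = None
) -> TranscriptChain:
    """Pick the chain maximising matched bases over compatible segments.

    Compatibility means non-overlap in transcript coordinates. This is
    weighted interval scheduling, solved exactly by dynamic programming over
    segments sorted by q_end. Ties are broken toward fewer segments and then
    earlier genomic coordinates for determinism.
    """
    if not segments:
        raise ValueError("select_optimal_chain requires at least one segment")
    tid = segments[0].transcript_id
    length = transcript_length if transcript_length is not None else max(
        s.q_end for s in segments
    )
    segs = sorted(segments, key=lambda s: (s.q_end, s.q_start, s.g_start))
    ends = [s.q_end for s in segs]
    n = len(segs)
    # best[i] = (score, -count) achievable using segs[:i]
    best: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    take: list[bool] = [False] * n
    prev_idx: list[int] = [0] * n
    for i, s in enumerate(segs):
        j = bisect.bisect_right(ends, s.q_start, 0, i)  # last compatible + 1
        prev_idx[i] = j
        with_i = (best[j][0] + s.matches, best[j][1] - 1)
        without_i = best[i]
        if with_i > without_i:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = without_i
    chosen: list[AlignmentSegment] = []
    i = n
    while i > 0:
        if take[i - 1] and best[i] != best[i - 1]:
            chosen.append(segs[i - 1])
            i = prev_idx[i - 1]
        else:
            i -= 1
    chosen.sort(key=lambda s: s.q_start)
    spans: list[tuple[int, int]] = []
    pos = 0
    for s in chosen:
        if s.q_start > pos:
            spans.append((pos, s.q_start))
        pos = s.q_end
    if pos < length:
        spans.append((pos, length))
    return TranscriptChain(tid, length, chosen, spans)


def group_chains(
    segments: Iterable[AlignmentSegment],
    transcript_lengths: Mapping[str, int] | None = None,
) -> dict[str, TranscriptChain]:
    by_tid: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for s in segments:
        by_tid[s.transcript_id].append(s)
    chains = {}
    for tid, segs in by_tid.items():
        tl = transcript_lengths.get(tid) if transcript_lengths else None
        chains[tid] = select_optimal_chain(segs, tl)
    return chains


# ---------------------------------------------------------------------------
# connection classification (multi-scaffold chains)
# ---------------------------------------------------------------------------

def _near_scaffold_tail(seg: AlignmentSegment, scaffold_len: int, tol: int) -> bool:
    return scaffold_len - seg.g_end <= tol


def _near_scaffold_head(seg: AlignmentSegment, tol: int) -> bool:
    return seg.g_start <= tol


def _join_transition_ok(
    a: AlignmentSegment, b: AlignmentSegment, scaffold_lengths: Mapping[str, int],
    edge_tol: int,
) -> bool:
    if a.strand != b.strand:
        return False
    if a.strand == "+":
        a_ok = _near_scaffold_tail(a, scaffold_lengths[a.scaffold_id], edge_tol)
        b_ok = _near_scaffold_head(b, edge_tol)
    else:
        a_ok = _near_scaffold_head(a, edge_tol)
        b_ok = _near_scaffold_tail(b, scaffold_lengths[b.scaffold_id], edge_tol)
    return a_ok and b_ok


def _gap_runs_between(
    gap_map: Mapping[str, Sequence[tuple[int, int]]],
    scaffold: str,
    lo: int,
    hi: int,
) -> list[tuple[int, int]]:
    return [
        (s, e)
        for s, e in gap_map.get(scaffold, ())
        if s < hi and e > lo
    ]


def classify_connection(
    chain: TranscriptChain,
    scaffold_lengths: Mapping[str, int],
    gap_map: Mapping[str, Sequence[tuple[int, int]]],
    edge_tol: int = 50,
) -> ConnectionCall:
    """Classify a multi-scaffold chain as OK_join, OK_merge or PB_merge.

    OK_merge: some scaffold's aligned span sits wholly within an N-run gap
    of the flanking scaffold (host - insert - host sandwich). OK_join: every
    cross-scaffold transition links two scaffold ends with consistent
    orientation. Anything else is PB_merge (likely mis-assembly).
    """
    if not chain.is_multi_scaffold():
        raise ValueError("classify_connection requires a multi-scaffold chain")
    segs = chain.segments
    pattern = chain.orientation_pattern

    # OK_merge: host / insert / host sandwich around an adequate N-run
    for i in range(1, len(segs) - 1):
        prev, mid, nxt = segs[i - 1], segs[i], segs[i + 1]
        if (
            prev.scaffold_id == nxt.scaffold_id != mid.scaffold_id
        ):
            lo = min(prev.g_end, nxt.g_end)
            hi = max(prev.g_start, nxt.g_start)
            if lo > hi:
                lo, hi = hi, lo
            span = mid.g_end - mid.g_start
            for gs, ge in _gap_runs_between(gap_map, prev.scaffold_id, lo, hi):
                if ge - gs >= span:
                    return ConnectionCall(
                        "OK_merge",
                        (prev.scaffold_id, mid.scaffold_id),
                        (chain.transcript_id,),
                        pattern,
                    )

    transitions = [
        (a, b)
        for a, b in zip(segs, segs[1:])
        if a.scaffold_id != b.scaffold_id
    ]
    if transitions and all(
        _join_transition_ok(a, b, scaffold_lengths, edge_tol)
        for a, b in transitions
    ):
        order = []
        for s in segs:
            if s.scaffold_id not in order:
                order.append(s.scaffold_id)
        return ConnectionCall("OK_join", tuple(order), (chain.transcript_id,), pattern)

    scafs = []
    for s in segs:
        if s.scaffold_id not in scafs:
            scafs.append(s.scaffold_id)
    return ConnectionCall("PB_merge", tuple(scafs), (chain.transcript_id,), pattern)


# ---------------------------------------------------------------------------
# within-scaffold detectors
# ---------------------------------------------------------------------------

def detect_strand_inconsistency(chain: TranscriptChain) -> list[ImprovementCall]:
    """Flag consecutive same-scaffold segment pairs violating order/strand.

    Ascending genome order must pair with "++", descending with "--"; every
    other combination is reported as a strand inconsistency.
    """
    calls = []
    for a, b in zip(chain.segments, chain.segments[1:]):
        if a.scaffold_id != b.scaffold_id:
            continue
        ascending = b.g_start >= a.g_start
        pattern = a.strand + b.strand
        consistent = (ascending and pattern == "++") or (
            not ascending and pattern == "--"
        )
        if not consistent:
            calls.append(
                ImprovementCall(
                    kind="strand_inconsistency",
                    transcript_id=chain.transcript_id,
                    scaffolds=(a.scaffold_id,),
                    coordinates=(
                        min(a.g_start, b.g_start),
                        max(a.g_end, b.g_end),
                    ),
                    orientation_pattern=pattern,
                    details={"order": "ascending" if ascending else "descending"},
                )
            )
    return calls


def detect_nested(
    chain: TranscriptChain, nest_min_overlap: int = 20
) -> list[ImprovementCall]:
    """Flag consecutive same-scaffold segments whose genome footprints overlap.

    Distinct transcript intervals re-aligning to one genome interval imply a
    collapsed repeat copy in the assembly.
    """
    calls = []
    for a, b in zip(chain.segments, chain.segments[1:]):
        if a.scaffold_id != b.scaffold_id:
            continue
        lo = max(a.g_start, b.g_start)
        hi = min(a.g_end, b.g_end)
        overlap = hi - lo
        if overlap >= nest_min_overlap:
            contained = (
                (b.g_start >= a.g_start and b.g_end <= a.g_end)
                or (a.g_start >= b.g_start and a.g_end <= b.g_end)
            )
            calls.append(
                ImprovementCall(
                    kind="nest",
                    transcript_id=chain.transcript_id,
                    scaffolds=(a.scaffold_id,),
                    coordinates=(lo, hi),
                    orientation_pattern=a.strand + b.strand,
                    details={"overlap": overlap, "containment": contained},
                )
            )
    return calls


def find_boundary_extensions(
    chain: TranscriptChain,
    scaffold_lengths: Mapping[str, int],
    transcript_seq: str | None = None,
    edge_tol: int = 50,
) -> list[ImprovementCall]:
    """Unaligned transcript ends abutting a scaffold end extend the boundary.

    The payload is the unaligned terminal transcript sequence oriented to the
    genome forward strand; ``details['side']`` records which scaffold end it
    extends.
    """
    if not chain.segments:
        return []
    calls = []
    first, last = chain.segments[0], chain.segments[-1]
    head = next(
        ((s, e) for s, e in chain.unaligned_spans if s == 0 and e == first.q_start),
        None,
    )
    tail = next(
        (
            (s, e)
            for s, e in chain.unaligned_spans
            if e == chain.transcript_length and s == last.q_end
        ),
        None,
    )

    def emit(seg: AlignmentSegment, span: tuple[int, int], upstream: bool) -> None:
        # upstream=True: the unaligned span precedes the segment in transcript
        # coordinates, so it extends past the genomic side the segment's
        # strand points back to.
        scaffold_len = scaffold_lengths[seg.scaffold_id]
        if (seg.strand == "+") == upstream:
            side = "left"
            if not _near_scaffold_head(seg, edge_tol):
                return
            anchor = seg.g_start
        else:
            side = "right"
            if not _near_scaffold_tail(seg, scaffold_len, edge_tol):
                return
            anchor = seg.g_end
        payload = None
        if transcript_seq is not None:
            payload = transcript_seq[span[0]: span[1]]
            if seg.strand == "-":
                payload = revcomp(payload)
        calls.append(
            ImprovementCall(
                kind="boundary_extension",
                transcript_id=chain.transcript_id,
                scaffolds=(seg.scaffold_id,),
                coordinates=(anchor,),
                orientation_pattern=seg.strand,
                payload=payload if payload is not None else "",
                details={"side": side, "length": span[1] - span[0]},
            )
        )

    if head is not None and head[1] > head[0]:
        emit(first, head, upstream=True)
    if tail is not None and tail[1] > tail[0]:
        emit(last, tail, upstream=False)
    return calls


def find_gap_closures(
    chain: TranscriptChain,
    gap_map: Mapping[str, Sequence[tuple[int, int]]],
    transcript_seq: str | None = None,
) -> list[ImprovementCall]:
    """Internal unaligned spans bridging an N-run become gap-closure calls.

    Records the transcript-derived fill length, the N-run's predicted gap
    length, and whether the two agree exactly.
    """
    calls = []
    span_by_start = {s: (s, e) for s, e in chain.unaligned_spans}
    for a, b in zip(chain.segments, chain.segments[1:]):
        if a.scaffold_id != b.scaffold_id or a.strand != b.strand:
            continue
        span = span_by_start.get(a.q_end)
        if span is None or span[1] != b.q_start:
            continue  # no unaligned transcript span between these segments
        if a.strand == "+":
            lo, hi = a.g_end, b.g_start
        else:
            lo, hi = b.g_end, a.g_start
        if lo >= hi:
            continue
        runs = _gap_runs_between(gap_map, a.scaffold_id, lo, hi)
        if not runs:
            continue
        gs, ge = runs[0]
        filled = span[1] - span[0]
        predicted = ge - gs
        payload = ""
        if transcript_seq is not None:
            payload = transcript_seq[span[0]: span[1]]
            if a.strand == "-":
                payload = revcomp(payload)
        calls.append(
            ImprovementCall(
                kind="gap_fill",
                transcript_id=chain.transcript_id,
                scaffolds=(a.scaffold_id,),
                coordinates=(gs, ge),
                orientation_pattern=a.strand + b.strand,
                payload=payload,
                details={
                    "filled_length": filled,
                    "predicted_gap_length": predicted,
                    "exact_match": filled == predicted,
                },
            )
        )
    return calls


# ---------------------------------------------------------------------------
# whole-fixture scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    chains: dict[str, TranscriptChain]
    connections: list[ConnectionCall]
    calls: list[ImprovementCall]

    def calls_of_kind(self, kind: str) -> list[ImprovementCall]:
        return [c for c in self.calls if c.kind == kind]

    def connection_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"OK_join": 0, "OK_merge": 0, "PB_merge": 0}
        for c in self.connections:
            counts[c.connection_class] += 1
        return counts


def _resolve_conflicting_joins(
    connections: list[ConnectionCall],
) -> list[ConnectionCall]:
    """Demote joins proposing incompatible neighbours for one scaffold pair.

    Join support is counted per unordered scaffold pair; when a scaffold end
    is claimed by several partners, the best-supported pair wins and ties
    demote all contenders to PB_merge.
    """
    joins = [c for c in connections if c.connection_class == "OK_join"]
    others = [c for c in connections if c.connection_class != "OK_join"]
    support: dict[frozenset, list[ConnectionCall]] = defaultdict(list)
    for c in joins:
        support[frozenset(c.scaffolds)].append(c)
    # claims per scaffold: which pairs want it
    claims: dict[str, set[frozenset]] = defaultdict(set)
    for pair in support:
        for scaf in pair:
            claims[scaf].add(pair)
    demoted: set[frozenset] = set()
    for scaf, pairs in claims.items():
        if len(pairs) <= 1:
            continue
        ranked = sorted(pairs, key=lambda p: -len(support[p]))
        if len(support[ranked[0]]) == len(support[ranked[1]]):
            demoted.update(pairs)  # tie: demote all contenders
        else:
            demoted.update(ranked[1:])
    out = others[:]
    for pair, calls in support.items():
        for c in calls:
            if pair in demoted:
                out.append(
                    ConnectionCall(
                        "PB_merge", c.scaffolds, c.supporting_transcripts,
                        c.orientation_pattern,
                    )
                )
            else:
                out.append(c)
    return out


def scan_alignments(
    segments: Iterable[AlignmentSegment],
    scaffold_lengths: Mapping[str, int],
    gap_map: Mapping[str, Sequence[tuple[int, int]]],
    transcripts: Mapping[str, str] | None = None,
    edge_tol: int = 50,
    nest_min_overlap: int = 20,
) -> ScanResult:
    """Run the full improvement scan over all transcript chains.

    Multi-scaffold chains are classified into connection classes (with
    OK_join / OK_merge mirrored as join / merge improvement calls and
    PB_merge as mis_scaffold reports); single-scaffold chains run the
    strand-inconsistency, nest, boundary-extension and gap-closure
    detectors.
    """
    lengths = {t: len(s) for t, s in transcripts.items()} if transcripts else None
    chains = group_chains(segments, lengths)
    connections: list[ConnectionCall] = []
    calls: list[ImprovementCall] = []
    for tid in sorted(chains):
        chain = chains[tid]
        seq = transcripts.get(tid) if transcripts else None
        if chain.is_multi_scaffold():
            connections.append(
                classify_connection(chain, scaffold_lengths, gap_map, edge_tol)
            )
        else:
            calls.extend(detect_strand_inconsistency(chain))
            calls.extend(detect_nested(chain, nest_min_overlap))
            calls.extend(
                find_boundary_extensions(chain, scaffold_lengths, seq, edge_tol)
            )
            calls.extend(find_gap_closures(chain, gap_map, seq))
    connections = _resolve_conflicting_joins(connections)
    kind_map = {"OK_join": "join", "OK_merge": "merge", "PB_merge": "mis_scaffold"}
    for conn in connections:
        calls.append(
            ImprovementCall(
                kind=kind_map[conn.connection_class],
                transcript_id=conn.supporting_transcripts[0],
                scaffolds=conn.scaffolds,
                coordinates=(),
                orientation_pattern=conn.orientation_pattern,
            )
        )
    return ScanResult(chains=chains, connections=connections, calls=calls)
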