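"""Minimal PSL (BLAT) 21-column format reader/writer.

PSL conventions honoured here:

* 21 tab-separated columns, optional 5-line ``psLayout`` header.
* Target (genome) coordinates are 0-based half-open and always on the
  forward strand.
* For ``-`` strand records the per-block ``qStarts`` are expressed in
  reverse-complemented query coordinates, while the record-level
  ``qStart``/``qEnd`` stay in forward query coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

__all__ = ["PslRecord", "read_psl", "write_psl"]

PSL_COLUMNS = 21


@dataclass
class PslRecord:
    matches: int
    mismatches: int
    rep_matches: int
    n_count: int
    q_num_insert: int
    q_base_insert: int
    t_num_insert: int
    t_base_insert: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_count: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]  # native convention (reversed coords on '-')
    t_starts: tuple[int, ...]

    def forward_query_blocks(self) -> list[tuple[int, int, int, int]]:
        """Blocks as (q_start, q_end, t_start, t_end) in forward query coords.

        Returned in target order (the stored block order).
        """
        out = []
        for bs, qs, ts in zip(self.block_sizes, self.q_starts, self.t_starts):
            if self.strand == "+":
                out.append((qs, qs + bs, ts, ts + bs))
            else:
                out.append((self.q_size - qs - bs, self.q_size - qs, ts, ts + bs))
        return out


def _parse_csv_ints(field: str) -> tuple[int, ...]:
    return tuple(int(x) for x in field.rstrip(",").split(",") if x)


def read_psl(handle: TextIO | str) -> Iterator[PslRecord]:
    """Parse a PSL file; raises ValueError with the line number on bad rows."""
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            # skip psLayout headers
            if line.startswith(("psLayout", "match", "-----", " ")):
                continue
            fields = line.split("\t")
            if len(fields) != PSL_COLUMNS:
                raise ValueError(
                    f"PSL line {lineno}: expected {PSL_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            yield PslRecord(
                matches=int(fields[0]),
                mismatches=int(fields[1]),
                rep_matches=int(fields[2]),
                n_count=int(fields[3]),
                q_num_insert=int(fields[4]),
                q_base_insert=int(fields[5]),
                t_num_insert=int(fields[6]),
                t_base_insert=int(fields[7]),
                strand=fields[8],
                q_name=fields[9],
                q_size=int(fields[10]),
                q_start=int(fields[11]),
                q_end=int(fields[12]),
                t_name=fields[13],
                t_size=int(fields[14]),
                t_start=int(fields[15]),
                t_end=int(fields[16]),
                block_count=int(fields[17]),
                block_sizes=_parse_csv_ints(fields[18]),
                q_starts=_parse_csv_ints(fields[19]),
                t_starts=_parse_csv_ints(fields[20]),
            )
    finally:
        if close:
            handle.close()


def make_record(
    q_name: str,
    q_size: int,
    t_name: str,
    t_size: int,
    strand: str,
    blocks: list[tuple[int, int]],
    block_sizes: list[int],
) -> PslRecord:
    """Build a gapless-block PSL record from forward-query block starts.

    ``blocks`` holds (q_start_forward, t_start) per block; block order must
    be ascending in target coordinates.
    """
    assert strand in "+-"
    q_starts = []
    for (qf, _), bs in zip(blocks, block_sizes):
        q_starts.append(qf if strand == "+" else q_size - qf - bs)
    t_starts = [t for _, t in blocks]
    q_lo = min(qf for qf, _ in blocks)
    q_hi = max(qf + bs for (qf, _), bs in zip(blocks, block_sizes))
    return PslRecord(
        matches=sum(block_sizes),
        mismatches=0,
        rep_matches=0,
        n_count=0,
        q_num_insert=0,
        q_base_insert=0,
        t_num_insert=0,
        t_base_insert=0,
        strand=strand,
        q_name=q_name,
        q_size=q_size,
        q_start=q_lo,
        q_end=q_hi,
        t_name=t_name,
        t_size=t_size,
        t_start=min(t_starts),
        t_end=max(t + bs for t, bs in zip(t_starts, block_sizes)),
        block_count=len(block_sizes),
        block_sizes=tuple(block_sizes),
        q_starts=tuple(q_starts),
        t_starts=tuple(t_starts),
    )


def write_psl(records: Iterable[PslRecord], handle: TextIO) -> int:
    n = 0
    for r in records:
        fields = [
            r.matches, r.mismatches, r.rep_matches, r.n_count,
            r.q_num_insert, r.q_base_insert, r.t_num_insert, r.t_base_insert,
            r.strand, r.q_name, r.q_size, r.q_start, r.q_end,
            r.t_name, r.t_size, r.t_start, r.t_end, r.block_count,
            ",".join(map(str, r.block_sizes)) + ",",
            ",".join(map(str, r.q_starts)) + ",",
            ",".join(map(str, r.t_starts)) + ",",
        ]
        handle.write("\t".join(map(str, fields)) + "\n")
        n += 1
    return n
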