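"""Small GTF and BED readers/writers for the attribute-light files the
pipeline exchanges (gene models, assembled transcripts with FPKM, repeats).

GTF coordinates are 1-based closed on disk and converted to 0-based
half-open in memory; BED is 0-based half-open both ways.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

__all__ = ["GtfTranscript", "read_gtf", "write_gtf", "read_bed", "write_bed"]

_ATTR = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class GtfTranscript:
    transcript_id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    def fpkm_by_tissue(self) -> dict[str, float]:
        """Attributes of the form FPKM_<tissue> (or a bare FPKM) as floats."""
        out = {}
        for key, val in self.attributes.items():
            if key == "FPKM":
                out["pooled"] = float(val)
            elif key.startswith("FPKM_"):
                out[key[5:]] = float(val)
        return out


def read_gtf(handle: TextIO | str) -> list[GtfTranscript]:
    """Group exon features into transcripts (exons sorted by start)."""
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    by_tid: dict[str, GtfTranscript] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 columns")
            scaffold, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attributes = dict(_ATTR.findall(attrs))
            tid = attributes.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF line {lineno}: missing transcript_id")
            exon = (int(start) - 1, int(end))
            rec = by_tid.get(tid)
            if rec is None:
                by_tid[tid] = GtfTranscript(
                    transcript_id=tid,
                    gene_id=attributes.get("gene_id", tid),
                    scaffold=scaffold,
                    strand=strand,
                    exons=[exon],
                    attributes=attributes,
                )
            else:
                rec.exons.append(exon)
    finally:
        if close:
            handle.close()
    for rec in by_tid.values():
        rec.exons.sort()
    return list(by_tid.values())


def write_gtf(transcripts: Iterable[GtfTranscript], handle: TextIO) -> int:
    n = 0
    for t in transcripts:
        extra = "".join(
            f' {k} "{v}";'
            for k, v in t.attributes.items()
            if k not in ("gene_id", "transcript_id")
        )
        for s, e in t.exons:
            handle.write(
                f"{t.scaffold}\ttxrefine\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";{extra}\n'
            )
            n += 1
    return n


def read_bed(handle: TextIO | str) -> dict[str, list[tuple[int, int]]]:
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    out: dict[str, list[tuple[int, int]]] = {}
    try:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    finally:
        if close:
            handle.close()
    for v in out.values():
        v.sort()
    return out


def write_bed(intervals: Mapping[str, Iterable[tuple[int, int]]], handle: TextIO) -> int:
    n = 0
    for sid in sorted(intervals):
        for s, e in intervals[sid]:
            handle.write(f"{sid}\t{s}\t{e}\n")
            n += 1
    return n
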