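"""Read quality control: five low-quality rules, 50-nt trimming, pair routing.

Short-read RNA-seq libraries from early Illumina instruments show a steep
base-quality decline toward the 3' end. The filter applied here rejects a
read when any of five rules fires:

1. an ``N`` occurs within the first 30 nt;
2. more than 3 bases have quality < 10;
3. more than 4 bases have quality < 13;
4. more than 60% of bases have quality < 20;
5. the mean base quality is < 20.

Surviving reads are trimmed to a uniform length (default 50 nt) from the
5' end, since miscalls concentrate at the 3' end. Pairs where only one
mate survives contribute an orphan single-end read rather than being lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

__all__ = [
    "Read",
    "QCVerdict",
    "QCParams",
    "evaluate_read",
    "trim_read",
    "filter_pairs",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    failed_rules: frozenset[int]

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_rules)


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the five rules; defaults are the published values."""

    n_window: int = 30          # rule 1: leading window scanned for N
    q10_max: int = 3            # rule 2: max allowed bases with q < 10
    q13_max: int = 4            # rule 3: max allowed bases with q < 13
    q20_frac_max: float = 0.60  # rule 4: max fraction of bases with q < 20
    mean_q_min: float = 20.0    # rule 5: min mean quality


def evaluate_read(read: Read, params: QCParams = QCParams()) -> QCVerdict:
    """Apply all five low-quality rules; every failing rule is reported.

    Rule positions are 1-based: "the first 30 nt" means positions 1..30
    inclusive.
    """
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    failed: set[int] = set()
    if "N" in read.sequence[: params.n_window]:
        failed.add(1)
    quals = read.qualities
    if sum(q < 10 for q in quals) > params.q10_max:
        failed.add(2)
    if sum(q < 13 for q in quals) > params.q13_max:
        failed.add(3)
    if sum(q < 20 for q in quals) / len(quals) > params.q20_frac_max:
        failed.add(4)
    if sum(quals) / len(quals) < params.mean_q_min:
        failed.add(5)
    return QCVerdict(passed=not failed, failed_rules=frozenset(failed))


def trim_read(read: Read, target_len: int = 50) -> Read:
    """Keep the 5'-most ``target_len`` bases (qualities trimmed in step)."""
    if len(read) < target_len:
        raise ValueError(
            f"read {read.id!r} length {len(read)} < target length {target_len}"
        )
    return Read(read.id, read.sequence[:target_len], read.qualities[:target_len])


@dataclass
class PairFilterResult:
    kept_pairs: list[tuple[Read, Read]] = field(default_factory=list)
    orphan_singles: list[Read] = field(default_factory=list)
    discarded: list[Read] = field(default_factory=list)
    rule_failures: dict[int, int] = field(
        default_factory=lambda: {r: 0 for r in (1, 2, 3, 4, 5)}
    )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "kept_pairs": len(self.kept_pairs),
            "orphan_singles": len(self.orphan_singles),
            "discarded_reads": len(self.discarded),
        }


def _pair_key(read_id: str) -> str:
    # FASTQ pairing convention: strip a trailing /1 or /2 mate suffix
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def filter_pairs(
    pairs: Iterable[tuple[Read, Read]],
    params: QCParams = QCParams(),
    target_len: int | None = 50,
) -> PairFilterResult:
    """QC both mates, then trim survivors and route them to output bins.

    Both mates pass -> kept pair; exactly one passes -> orphan single;
    neither -> both discarded. Read count is conserved across bins:
    2*kept_pairs + orphans + discarded == total input reads.
    """
    result = PairFilterResult()
    for r1, r2 in pairs:
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValueError(f"unpaired records: {r1.id!r} vs {r2.id!r}")
        verdicts = [evaluate_read(r1, params), evaluate_read(r2, params)]
        for v in verdicts:
            for rule in v.failed_rules:
                result.rule_failures[rule] += 1
        survivors = []
        for read, v in zip((r1, r2), verdicts):
            if v.passed:
                survivors.append(
                    trim_read(read, target_len) if target_len else read
                )
            else:
                result.discarded.append(read)
        if len(survivors) == 2:
            result.kept_pairs.append((survivors[0], survivors[1]))
        elif len(survivors) == 1:
            result.orphan_singles.append(survivors[0])
    return result


def read_fastq(handle: TextIO | str, offset: int = 33) -> Iterator[Read]:
    """Iterate a FASTQ file as Read records (Phred+33 by default)."""
    shift = offset - 33  # Biopython decodes assuming Phred+33
    for rec in SeqIO.parse(handle, "fastq"):
        quals = tuple(q - shift for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq), quals)


def write_fastq(reads: Iterable[Read], handle: TextIO) -> int:
    n = 0
    for read in reads:
        qual = "".join(chr(q + 33) for q in read.qualities)
        handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
        n += 1
    return n
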