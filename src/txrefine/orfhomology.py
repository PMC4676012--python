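"""ORF completeness filtering, homology thresholds and gene tier calls.

A candidate novel gene survives as *full-length* only when its predicted ORF
carries a start codon, a stop codon and a CDS strictly longer than 150 bp.
Homology search hits against protein (nr), nucleotide (nt) and EST (dbEST)
databases are filtered at e-value <= 1e-5 with minimum alignment lengths of
10 aa (protein) / 20 nt (nucleotide), then aggregated per target sequence
into a coverage percentage; a database supports the gene when some target
reaches >= 95% coverage. The surviving genes fall into three tiers:

* ``homology_based`` — protein (nr) or cDNA (nt) support;
* ``unknown``        — EST (dbEST) support only;
* ``hypothetical``   — complete ORF, no qualifying homology anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "OrfRecord",
    "HomologyHit",
    "TierCall",
    "HomologyThresholds",
    "find_orfs",
    "orf_is_full_length",
    "hit_passes_thresholds",
    "target_coverage",
    "antisense_strand_check",
    "classify_tier",
    "evaluate_evidence",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

PROTEIN_DBS = {"nr"}
NUCLEOTIDE_DBS = {"nt", "dbEST"}


@dataclass(frozen=True)
class OrfRecord:
    transcript_id: str
    cds_start: int
    cds_end: int  # 0-based half-open, transcript coordinates
    strand: str
    has_start_codon: bool
    has_stop_codon: bool

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    database: str  # nr | nt | dbEST
    evalue: float
    target_id: str
    target_length: int  # residues for nr, nt for nucleotide databases
    align_start: int
    align_end: int  # target coordinates, 0-based half-open
    gap_size: int = 0

    def __post_init__(self) -> None:
        assert self.align_start < self.align_end <= self.target_length
        assert self.gap_size >= 0 and self.evalue >= 0

    @property
    def align_len(self) -> int:
        return self.align_end - self.align_start


@dataclass(frozen=True)
class TierCall:
    tier: str  # homology_based | unknown | hypothetical |
    #           rejected_partial | rejected_small
    evidence: Mapping[str, bool] = field(
        default_factory=lambda: {"nr": False, "nt": False, "dbEST": False}
    )


@dataclass(frozen=True)
class HomologyThresholds:
    max_evalue: float = 1e-5
    min_nt_align: int = 20
    min_aa_align: int = 10
    min_coverage: float = 95.0
    min_cds: int = 150


def find_orfs(sequence: str, transcript_id: str = "") -> list[OrfRecord]:
    """Naive six-frame ORF scan, longest first (fixture/utility use only).

    Reports, per strand and frame, each maximal ATG..stop span, plus
    open-ended spans lacking the stop codon (flagged incomplete).
    """
    from .txalign import revcomp

    orfs: list[OrfRecord] = []
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            i = frame
            start: int | None = None
            while i + 3 <= len(seq):
                codon = seq[i: i + 3]
                if start is None and codon == START_CODON:
                    start = i
                elif start is not None and codon in STOP_CODONS:
                    s, e = start, i + 3
                    if strand == "-":
                        s, e = n - e, n - s
                    orfs.append(
                        OrfRecord(transcript_id, s, e, strand, True, True)
                    )
                    start = None
                i += 3
            if start is not None:  # ran off the 3' end without a stop
                e = len(seq) - (len(seq) - start) % 3
                s = start
                if strand == "-":
                    s, e = n - e, n - s
                orfs.append(OrfRecord(transcript_id, s, e, strand, True, False))
    orfs.sort(key=lambda o: (-o.cds_length, o.cds_start, o.strand))
    return orfs


def orf_is_full_length(
    orf: OrfRecord, thresholds: HomologyThresholds = HomologyThresholds()
) -> str:
    """'full_length', or the rejection label 'rejected_partial'/'rejected_small'.

    Missing either codon marks a partial gene; a CDS not strictly longer
    than 150 bp marks a small gene. The partial label takes precedence.
    """
    if not (orf.has_start_codon and orf.has_stop_codon):
        return "rejected_partial"
    if orf.cds_length <= thresholds.min_cds:
        return "rejected_small"
    return "full_length"


def hit_passes_thresholds(
    hit: HomologyHit, thresholds: HomologyThresholds = HomologyThresholds()
) -> bool:
    """e-value and unit-appropriate minimum alignment length filter."""
    if hit.database in PROTEIN_DBS:
        min_len = thresholds.min_aa_align
    elif hit.database in NUCLEOTIDE_DBS:
        min_len = thresholds.min_nt_align
    else:
        raise ValueError(f"unknown homology database {hit.database!r}")
    return hit.evalue <= thresholds.max_evalue and hit.align_len >= min_len


def _merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def target_coverage(hits: Sequence[HomologyHit], merge: bool = True) -> float:
    """Percent of one target sequence covered by clustered hits.

    coverage = 100 * (sum of aligned target span - gapped positions)
               / target length

    With ``merge=True`` (default) overlapping target intervals are merged
    before summation so overlap is not double-counted; the raw additive
    value (which can exceed 100 before capping) is available with
    ``merge=False``. The result is capped to [0, 100].
    """
    if not hits:
        return 0.0
    tlen = hits[0].target_length
    assert all(
        h.target_id == hits[0].target_id and h.database == hits[0].database
        for h in hits
    ), "coverage is defined per query/target/database triple"
    gap_total = sum(h.gap_size for h in hits)
    if merge:
        covered = sum(
            e - s for s, e in _merge_intervals((h.align_start, h.align_end) for h in hits)
        )
    else:
        covered = sum(h.align_len for h in hits)
    pct = 100.0 * max(covered - gap_total, 0) / tlen
    return min(pct, 100.0)


def antisense_strand_check(alignment_strand: str, is_antisense: bool) -> bool:
    """Antisense candidates must align to the genome on the '+' strand.

    Applied only to candidates overlapping a known model on the opposite
    strand; all other candidates pass vacuously.
    """
    if not is_antisense:
        return True
    return alignment_strand == "+"


def _db_supported(
    hits: Sequence[HomologyHit], thresholds: HomologyThresholds
) -> bool:
    """A database supports a query if some target reaches the coverage bar."""
    passing = [h for h in hits if hit_passes_thresholds(h, thresholds)]
    by_target: dict[str, list[HomologyHit]] = {}
    for h in passing:
        by_target.setdefault(h.target_id, []).append(h)
    return any(
        target_coverage(th) >= thresholds.min_coverage
        for th in by_target.values()
    )


def classify_tier(
    orf: OrfRecord,
    hits_by_db: Mapping[str, Sequence[HomologyHit]],
    thresholds: HomologyThresholds = HomologyThresholds(),
) -> TierCall:
    """Assign one of the three tiers (or a rejection) to a predicted ORF.

    Protein (nr) or cDNA (nt) support makes the gene homology-based; EST
    support alone makes it unknown; a complete ORF without any qualifying
    support is hypothetical.
    """
    verdict = orf_is_full_length(orf, thresholds)
    if verdict != "full_length":
        return TierCall(tier=verdict)
    evidence = {
        db: _db_supported(hits_by_db.get(db, ()), thresholds)
        for db in ("nr", "nt", "dbEST")
    }
    if evidence["nr"] or evidence["nt"]:
        tier = "homology_based"
    elif evidence["dbEST"]:
        tier = "unknown"
    else:
        tier = "hypothetical"
    return TierCall(tier=tier, evidence=evidence)


def evaluate_evidence(
    orfs: Mapping[str, OrfRecord],
    hits: Iterable[HomologyHit],
    thresholds: HomologyThresholds = HomologyThresholds(),
) -> dict[str, TierCall]:
    """Tier-classify every ORF given a pooled homology-hit stream."""
    by_query: dict[str, dict[str, list[HomologyHit]]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, {}).setdefault(h.database, []).append(h)
    return {
        qid: classify_tier(orf, by_query.get(qid, {}), thresholds)
        for qid, orf in orfs.items()
    }
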