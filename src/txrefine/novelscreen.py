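"""Candidate novel transcript screening.

Assembled transcripts reach novel-gene candidacy through two branches:
*reference-free* (transcripts that failed to align to the draft genome at
all — possible missing assembly) and *reference-dependent* (aligned
transcripts, from either the de novo or the reference-based assembler, that
do not correspond to any known gene model). This module implements the
screening stages shared by both branches:

* greedy sequence-identity clustering with longest-representative selection
  (cd-hit-est-like: -c 0.95, -aS 0.95, -l 100, -g 1);
* ncRNA-hit removal;
* transcribed-locus building from same-strand exon overlaps;
* classification against known gene models (match / overlap / intergenic /
  intronic / antisense) with a repeat-fraction rejection;
* the FPKM >= 1 abundance floor for reference-based assemblies;
* cross-branch merging with longest-retained de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
from intervaltree import IntervalTree

from .gtfio import GtfTranscript

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateTranscript",
    "Locus",
    "Cluster",
    "ModelIndex",
    "greedy_identity_cluster",
    "remove_ncrna_hits",
    "build_loci",
    "classify_vs_models",
    "fpkm_filter",
    "merge_candidate_sets",
]

NOVEL_TAGS = {"intergenic_novel", "intronic_novel", "antisense_novel"}


@dataclass
class CandidateTranscript:
    id: str
    source: str  # denovo_unaligned | denovo_aligned | reference_based
    sequence: str | None = None
    scaffold: str | None = None
    strand: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    fpkm: dict[str, float] = field(default_factory=dict)
    tag: str | None = None

    @property
    def length(self) -> int:
        if self.exons:
            return sum(e - s for s, e in self.exons)
        return len(self.sequence or "")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @classmethod
    def from_gtf(cls, t: GtfTranscript, source: str) -> "CandidateTranscript":
        return cls(
            id=t.transcript_id,
            source=source,
            scaffold=t.scaffold,
            strand=t.strand,
            exons=list(t.exons),
            fpkm=t.fpkm_by_tissue(),
        )


@dataclass
class Cluster:
    representative: str
    members: list[str]


@dataclass
class Locus:
    members: list[str]
    representative: str
    span: tuple[str, int, int]  # scaffold, start, end


# ---------------------------------------------------------------------------
# sequence-identity clustering
# ---------------------------------------------------------------------------

def _pair_identity(short_seq: str, long_seq: str) -> float:
    """Identity of the shorter sequence aligned infix into the longer."""
    res = edlib.align(short_seq, long_seq, mode="HW", task="distance")
    return (len(short_seq) - res["editDistance"]) / len(short_seq)


def greedy_identity_cluster(
    sequences: Mapping[str, str],
    identity: float = 0.95,
    short_coverage: float = 0.95,
    min_len: int = 100,
) -> tuple[list[Cluster], int]:
    """Greedy descending-length clustering; longest member represents.

    A sequence joins the first existing cluster whose representative it
    matches at >= ``identity`` over >= ``short_coverage`` of the shorter
    sequence (the infix alignment model aligns the shorter sequence
    entirely, so coverage is satisfied whenever the identity bar is met over
    it). Sequences below ``min_len`` are dropped with a logged count.
    Representative ties on length break to the lexicographically smallest id.
    """
    items = [(tid, seq) for tid, seq in sequences.items() if len(seq) >= min_len]
    n_dropped = len(sequences) - len(items)
    if n_dropped:
        logger.info("dropped %d sequences shorter than %d nt", n_dropped, min_len)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[list[str]] = []
    rep_seqs: list[str] = []
    for tid, seq in items:
        placed = False
        for ci, rep_seq in enumerate(rep_seqs):
            short, long_ = (seq, rep_seq) if len(seq) <= len(rep_seq) else (rep_seq, seq)
            if _pair_identity(short, long_) >= identity:
                clusters[ci].append(tid)
                placed = True
                break
        if not placed:
            clusters.append([tid])
            rep_seqs.append(seq)
    out = []
    for members in clusters:
        rep = min(members, key=lambda t: (-len(sequences[t]), t))
        out.append(Cluster(representative=rep, members=sorted(members)))
    return out, n_dropped


def remove_ncrna_hits(
    representatives: Iterable[str],
    ncrna_hits: Iterable[Mapping],
    max_evalue: float = 1e-5,
) -> tuple[set[str], set[str]]:
    """Drop representatives with a qualifying non-coding RNA database hit.

    Returns (kept, removed). Hits naming unknown transcripts are ignored
    with a warning; a hit qualifies when its e-value (if reported) clears
    the threshold.
    """
    reps = set(representatives)
    removed: set[str] = set()
    for hit in ncrna_hits:
        tid = hit["transcript_id"]
        if tid not in reps:
            logger.warning("ncRNA hit for unknown transcript %s ignored", tid)
            continue
        if float(hit.get("evalue", 0.0)) <= max_evalue:
            removed.add(tid)
    return reps - removed, removed


def candidates_from_psl(records, source: str) -> list[CandidateTranscript]:
    """Turn single-scaffold, single-strand PSL alignments into candidates.

    Block intervals become exons (adjacent/overlapping target intervals
    merged); transcripts whose records disagree on scaffold or strand are
    skipped — their structural evidence belongs to the assembly-improvement
    scan, not to gene screening.
    """
    by_tid: dict[str, list] = {}
    for rec in records:
        by_tid.setdefault(rec.q_name, []).append(rec)
    out = []
    for tid in sorted(by_tid):
        recs = by_tid[tid]
        if len({(r.t_name, r.strand) for r in recs}) != 1:
            continue
        intervals = sorted(
            (ts, ts + bs)
            for r in recs
            for ts, bs in zip(r.t_starts, r.block_sizes)
        )
        exons: list[tuple[int, int]] = []
        for s, e in intervals:
            if exons and s <= exons[-1][1]:
                exons[-1] = (exons[-1][0], max(exons[-1][1], e))
            else:
                exons.append((s, e))
        out.append(
            CandidateTranscript(
                id=tid,
                source=source,
                scaffold=recs[0].t_name,
                strand=recs[0].strand,
                exons=exons,
            )
        )
    return out


# ---------------------------------------------------------------------------
# locus building / merging (exon-overlap connectivity)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self) -> dict[str, list[str]]:
        comps: dict[str, list[str]] = {}
        for x in self.parent:
            comps.setdefault(self.find(x), []).append(x)
        return comps


def _exon_overlap_components(
    transcripts: Sequence[CandidateTranscript],
) -> dict[str, list[str]]:
    """Connected components of the same-strand exon-overlap graph.

    Implemented as a sweep over exon intervals per (scaffold, strand): an
    exon starting before the running maximum end overlaps some exon already
    in the current run, so their transcripts share a component.
    """
    uf = _UnionFind()
    by_group: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for t in transcripts:
        uf.add(t.id)
        for s, e in t.exons:
            by_group.setdefault((t.scaffold, t.strand), []).append((s, e, t.id))
    for exons in by_group.values():
        exons.sort()
        run_owner: str | None = None
        run_end = -1
        for s, e, tid in exons:
            if run_owner is not None and s < run_end:
                uf.union(run_owner, tid)
                run_end = max(run_end, e)
            else:
                run_owner = tid
                run_end = e
            run_owner = uf.find(run_owner)
    return uf.components()


def build_loci(transcripts: Sequence[CandidateTranscript]) -> list[Locus]:
    """Group aligned transcripts into transcribed loci by exon overlap.

    Overlap must share the strand; grouping is transitive. The longest
    member (ties to smallest id) represents the locus.
    """
    by_id = {t.id: t for t in transcripts}
    loci = []
    for members in _exon_overlap_components(transcripts).values():
        rep = min(members, key=lambda t: (-by_id[t].length, t))
        scaffold = by_id[rep].scaffold
        start = min(by_id[m].span[0] for m in members)
        end = max(by_id[m].span[1] for m in members)
        loci.append(Locus(sorted(members), rep, (scaffold, start, end)))
    loci.sort(key=lambda l: l.span)
    return loci


def merge_candidate_sets(
    set_a: Sequence[CandidateTranscript], set_b: Sequence[CandidateTranscript]
) -> list[CandidateTranscript]:
    """Merge two candidate sets, de-duplicating repeatedly defined genes.

    Transcripts connected by exon overlap across (or within) the sets
    collapse to their longest member; non-overlapping transcripts pass
    through unchanged.
    """
    all_t = list(set_a) + list(set_b)
    by_id = {t.id: t for t in all_t}
    if len(by_id) != len(all_t):
        raise ValueError("duplicate transcript ids across candidate sets")
    kept = []
    for members in _exon_overlap_components(all_t).values():
        rep = min(members, key=lambda t: (-by_id[t].length, t))
        kept.append(by_id[rep])
    kept.sort(key=lambda t: t.id)
    return kept


# ---------------------------------------------------------------------------
# classification against known gene models
# ---------------------------------------------------------------------------

class ModelIndex:
    """Known gene models indexed for exon/intron/span interval queries."""

    def __init__(self, models: Sequence[GtfTranscript], flank: int = 5000):
        self.flank = flank
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        self.intron_chains: dict[tuple[str, str], set] = {}
        self.mono_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
        self.introns: dict[str, list[tuple[int, int, str]]] = {}
        self.scaffolds_with_models: set[str] = set()
        for m in models:
            key = (m.scaffold, m.strand)
            self.scaffolds_with_models.add(m.scaffold)
            tree = self.exons.setdefault(key, IntervalTree())
            for s, e in m.exons:
                tree.addi(s, e, m.transcript_id)
            self.spans.setdefault(m.scaffold, IntervalTree()).addi(
                m.start, m.end, m.transcript_id
            )
            chain = m.intron_chain
            if chain:
                self.intron_chains.setdefault(key, set()).add(chain)
                for s, e in chain:
                    self.introns.setdefault(m.scaffold, []).append((s, e, m.strand))
            else:
                self.mono_exons.setdefault(key, []).append(m.exons[0])

    def exon_overlap(self, t: CandidateTranscript, strand: str) -> bool:
        tree = self.exons.get((t.scaffold, strand))
        if tree is None:
            return False
        return any(tree.overlap(s, e) for s, e in t.exons)

    def near_model(self, t: CandidateTranscript) -> bool:
        tree = self.spans.get(t.scaffold)
        if tree is None:
            return False
        s, e = t.span
        return bool(tree.overlap(s - self.flank, e + self.flank))

    def matches_model(self, t: CandidateTranscript, min_mono_overlap: float = 0.90) -> bool:
        key = (t.scaffold, t.strand)
        chain = t.intron_chain
        if chain:
            return chain in self.intron_chains.get(key, set())
        ts, te = t.span
        for ms, me in self.mono_exons.get(key, ()):
            ov = min(te, me) - max(ts, ms)
            if ov > 0 and ov >= min_mono_overlap * (te - ts) and ov >= min_mono_overlap * (me - ms):
                return True
        return False

    def within_intron(self, t: CandidateTranscript) -> bool:
        ts, te = t.span
        return any(
            s <= ts and te <= e for s, e, _ in self.introns.get(t.scaffold, ())
        )


def _repeat_fraction(
    t: CandidateTranscript, repeats: Mapping[str, Sequence[tuple[int, int]]]
) -> float:
    """Fraction of the transcript's exonic bases lying in repeat intervals."""
    runs = repeats.get(t.scaffold, ())
    if not runs:
        return 0.0
    covered = 0
    for es, ee in t.exons:
        for rs, re_ in runs:
            lo, hi = max(es, rs), min(ee, re_)
            if lo < hi:
                covered += hi - lo
    return covered / t.length if t.length else 0.0


def classify_vs_models(
    transcript: CandidateTranscript,
    index: ModelIndex,
    repeats: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    repeat_frac_max: float = 0.50,
) -> str:
    """Tag an aligned transcript against the known gene models.

    Order of precedence: match (shared intron chain / reciprocal mono-exon
    overlap), overlap_known (same-strand exonic overlap, or proximity within
    the intergenic flank), repeat_rejected (>= half the exonic bases
    repeat-masked), intronic_novel (wholly inside a model intron, no exon
    overlap), antisense_novel (exonic overlap on the opposite strand only),
    intergenic_novel otherwise. Scaffolds carrying no model at all are
    intergenic by definition.
    """
    if not transcript.exons:
        raise ValueError(f"transcript {transcript.id} has no exons")
    t = transcript
    if t.scaffold in index.scaffolds_with_models:
        if index.matches_model(t):
            t.tag = "match"
            return t.tag
        same = index.exon_overlap(t, t.strand)
        opposite = index.exon_overlap(t, "-" if t.strand == "+" else "+")
        if same:
            t.tag = "overlap_known"
            return t.tag
        if repeats is not None and _repeat_fraction(t, repeats) >= repeat_frac_max:
            t.tag = "repeat_rejected"
            return t.tag
        if not opposite and index.within_intron(t):
            t.tag = "intronic_novel"
            return t.tag
        if opposite:
            t.tag = "antisense_novel"
            return t.tag
        if index.near_model(t):
            t.tag = "overlap_known"  # within the intergenic exclusion flank
            return t.tag
    elif repeats is not None and _repeat_fraction(t, repeats) >= repeat_frac_max:
        t.tag = "repeat_rejected"
        return t.tag
    t.tag = "intergenic_novel"
    return t.tag


def fpkm_filter(
    transcripts: Sequence[CandidateTranscript],
    min_fpkm: float = 1.0,
) -> tuple[list[CandidateTranscript], list[CandidateTranscript]]:
    """Keep transcripts whose best per-tissue FPKM reaches the floor.

    Abundance is max-pooled across tissues; transcripts with no abundance
    records are treated as 0 and removed. Returns (kept, removed); removed
    transcripts are tagged ``low_abundance_rejected``.
    """
    kept, removed = [], []
    for t in transcripts:
        best = max(t.fpkm.values()) if t.fpkm else 0.0
        if best >= min_fpkm:
            kept.append(t)
        else:
            t.tag = "low_abundance_rejected"
            removed.append(t)
    return kept, removed
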