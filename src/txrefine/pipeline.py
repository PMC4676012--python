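"""End-to-end drivers wiring the stage modules together over one dataset.

These functions operate on an in-memory :class:`~txrefine.fixtures.Fixture`
(or equivalent structures loaded from files) and are shared by the CLI, the
test-suite round trips and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import protvalid
from .fixtures import Fixture, align_exact, score_recovery
from .genomefix import (
    AssemblyStats,
    apply_improvements,
    assembly_stats,
    build_gap_map,
    gap_map_as_tuples,
)
from .novelscreen import (
    NOVEL_TAGS,
    CandidateTranscript,
    candidates_from_psl,
    classify_vs_models,
    fpkm_filter,
    greedy_identity_cluster,
    merge_candidate_sets,
    remove_ncrna_hits,
    ModelIndex,
)
from .orfhomology import antisense_strand_check, evaluate_evidence, TierCall
from .readqc import filter_pairs
from .txalign import ScanResult, scan_alignments, segments_from_record

__all__ = [
    "scan_fixture",
    "improve_fixture",
    "screen_fixture",
    "tier_fixture",
    "proteomic_validation",
    "ImprovementOutcome",
    "ScreenOutcome",
]


def scan_fixture(fix: Fixture, edge_tol: int = 50, nest_min_overlap: int = 20) -> ScanResult:
    """Improvement scan of a fixture's PSL alignments over its draft genome."""
    segments = [
        seg for rec in fix.psl_records for seg in segments_from_record(rec)
    ]
    scaffold_lengths = {sid: len(s) for sid, s in fix.draft_genome.items()}
    gap_map = gap_map_as_tuples(build_gap_map(fix.draft_genome))
    return scan_alignments(
        segments, scaffold_lengths, gap_map, transcripts=fix.transcripts,
        edge_tol=edge_tol, nest_min_overlap=nest_min_overlap,
    )


@dataclass
class ImprovementOutcome:
    scan: ScanResult
    improved_genome: dict[str, str]
    edit_log: list[dict]
    stats_before: AssemblyStats
    stats_after: AssemblyStats
    recovery: dict
    rescan: ScanResult

    def gap_fill_summary(self) -> dict:
        """Filled-length bookkeeping over accepted gap closures.

        Reports both the bp-weighted and the per-gap exact-match rate, since
        "exactly matched" can be read either way.
        """
        fills = self.scan.calls_of_kind("gap_fill")
        total = sum(c.details["filled_length"] for c in fills)
        exact_bp = sum(
            c.details["filled_length"] for c in fills if c.details["exact_match"]
        )
        n_exact = sum(bool(c.details["exact_match"]) for c in fills)
        return {
            "n_gaps_filled": len(fills),
            "filled_length_bp": total,
            "exact_match_rate_bp": 100.0 * exact_bp / total if total else 0.0,
            "exact_match_rate_count": 100.0 * n_exact / len(fills) if fills else 0.0,
        }


def improve_fixture(fix: Fixture, policy: str = "conservative") -> ImprovementOutcome:
    """Scan, edit, recompute stats, and re-scan the edited genome.

    The re-scan re-aligns the same transcripts against the improved genome
    with the exact aligner, verifying that accepted edits do not regenerate
    their own calls.
    """
    scan = scan_fixture(fix)
    improved, log = apply_improvements(fix.draft_genome, scan.calls, policy=policy)
    before = assembly_stats(fix.draft_genome)
    after = assembly_stats(improved)
    recovery = score_recovery(scan.calls, fix.truth)
    segments = align_exact(fix.transcripts, improved)
    scaffold_lengths = {sid: len(s) for sid, s in improved.items()}
    gap_map = gap_map_as_tuples(build_gap_map(improved))
    rescan = scan_alignments(
        segments, scaffold_lengths, gap_map, transcripts=fix.transcripts
    )
    return ImprovementOutcome(scan, improved, log, before, after, recovery, rescan)


@dataclass
class ScreenOutcome:
    tags: dict[str, str]                      # aligned transcript -> tag
    novel_denovo: list[CandidateTranscript]
    novel_reference: list[CandidateTranscript]
    merged: list[CandidateTranscript]
    low_abundance: list[CandidateTranscript]
    unaligned_representatives: set[str]
    ncrna_removed: set[str]
    n_unaligned_clusters: int


def screen_fixture(fix: Fixture) -> ScreenOutcome:
    """Both candidate branches: reference-free and reference-dependent."""
    index = ModelIndex(fix.gene_models)
    repeats = fix.repeats

    denovo = candidates_from_psl(fix.psl_records, "denovo_aligned")
    tags: dict[str, str] = {}
    novel_denovo = []
    for t in denovo:
        tag = classify_vs_models(t, index, repeats)
        if tag == "antisense_novel" and not antisense_strand_check(t.strand, True):
            tag = "overlap_known"  # antisense evidence only trusted on '+'
            t.tag = tag
        tags[t.id] = tag
        if tag in NOVEL_TAGS:
            novel_denovo.append(t)

    reference = [
        CandidateTranscript.from_gtf(g, "reference_based") for g in fix.abundance
    ]
    kept, low = fpkm_filter(reference)
    novel_reference = []
    for t in kept:
        tag = classify_vs_models(t, index, repeats)
        tags[t.id] = tag
        if tag in NOVEL_TAGS:
            novel_reference.append(t)

    merged = merge_candidate_sets(novel_denovo, novel_reference)

    clusters, _ = greedy_identity_cluster(fix.unaligned_transcripts)
    reps = {c.representative for c in clusters}
    kept_reps, removed = remove_ncrna_hits(
        reps, fix.ncrna_hits if isinstance(fix.ncrna_hits, list) else []
    )
    return ScreenOutcome(
        tags=tags,
        novel_denovo=novel_denovo,
        novel_reference=novel_reference,
        merged=merged,
        low_abundance=low,
        unaligned_representatives=kept_reps,
        ncrna_removed=removed,
        n_unaligned_clusters=len(clusters),
    )


def tier_fixture(fix: Fixture) -> dict[str, TierCall]:
    """Tier-classify every predicted ORF against the planted evidence tables."""
    return evaluate_evidence(fix.orfs, fix.homology_hits)


def proteomic_validation(
    fix: Fixture, tiers: dict[str, TierCall]
) -> list[protvalid.ValidationSummary]:
    """Per-tier proteomic validation over genes expressed in assayed tissues.

    A gene is "expressed" for this purpose when its abundance reaches 1 FPKM
    in at least one of the proteome-assayed tissues.
    """
    proteome_tissues = set(fix.tissues[: fix.config.n_proteome_tissues])
    fpkm_by_gene = {}
    for g in fix.abundance:
        if g.transcript_id.startswith("cuff_novel_"):
            gid = g.transcript_id[5:]  # cuff_<gene id>
            fpkm_by_gene[gid] = g.fpkm_by_tissue()
    expressed_by_group: dict[str, set[str]] = {}
    for g in fix.truth.novel_genes:
        call = tiers.get(g["transcript"])
        if call is None or call.tier not in ("homology_based", "unknown", "hypothetical"):
            continue
        fpkm = fpkm_by_gene.get(g["id"], {})
        if not any(v >= 1.0 for t, v in fpkm.items() if t in proteome_tissues):
            continue
        expressed_by_group.setdefault(call.tier, set()).add(g["id"])
    return protvalid.summarize_validation(fix.peptide_hits, expressed_by_group)


def qc_fixture(fix: Fixture):
    """Run read QC over the fixture's read pairs."""
    return filter_pairs(fix.read_pairs)
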