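"""Descriptive statistics over gene sets.

Covers the reporting the discovery pipeline ends with: tier counts and
fractions, per-gene GC content histogrammed at 5% steps, CDS length
histogrammed at 0.1 kb steps, expression breadth (tissues with FPKM >= 1),
and a two-sided Wilcoxon rank-sum comparison between distributions (e.g.
novel vs known gene GC or CDS length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneSetSummary",
    "gc_content",
    "expression_breadth",
    "summarize_gene_set",
    "compare_distributions",
]


@dataclass
class GeneSetSummary:
    n_genes: int
    tier_counts: dict[str, int]
    tier_fractions: dict[str, float]
    gc_histogram: dict[float, int]        # bin lower edge (%) -> count
    cds_length_histogram: dict[float, int]  # bin lower edge (kb) -> count
    expression_breadth_histogram: dict[int, int]
    gc_excluded: int  # genes with no unambiguous bases


def gc_content(sequence: str) -> float | None:
    """GC percentage over unambiguous bases; None if none are present."""
    counts = {b: sequence.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return None
    return 100.0 * (counts["G"] + counts["C"]) / denom


def expression_breadth(fpkm_by_tissue: Mapping[str, float], min_fpkm: float = 1.0) -> int:
    """Number of tissues in which the gene reaches the abundance floor."""
    return sum(v >= min_fpkm for v in fpkm_by_tissue.values())


def _histogram(values: Sequence[float], step: float) -> dict[float, int]:
    hist: dict[float, int] = {}
    for v in values:
        edge = round(np.floor(v / step) * step, 10)
        hist[edge] = hist.get(edge, 0) + 1
    return dict(sorted(hist.items()))


def summarize_gene_set(
    sequences: Mapping[str, str],
    tiers: Mapping[str, str],
    fpkm: Mapping[str, Mapping[str, float]] | None = None,
    gc_step: float = 5.0,
    cds_step_kb: float = 0.1,
    min_fpkm: float = 1.0,
) -> GeneSetSummary:
    """GC/CDS-length/breadth histograms and tier fractions for one gene set.

    ``sequences`` maps gene id to CDS sequence; genes whose sequence has no
    unambiguous bases are excluded from the GC histogram and counted.
    """
    n = len(sequences)
    tier_counts: dict[str, int] = {}
    for gid in sequences:
        tier = tiers.get(gid, "unassigned")
        tier_counts[tier] = tier_counts.get(tier, 0) + 1
    assigned = sum(tier_counts.values())
    tier_fractions = {
        t: round(100.0 * c / assigned, 2) for t, c in tier_counts.items()
    } if assigned else {}

    gcs, excluded = [], 0
    for seq in sequences.values():
        gc = gc_content(seq)
        if gc is None:
            excluded += 1
        else:
            gcs.append(gc)
    lengths_kb = [len(s) / 1000.0 for s in sequences.values()]
    breadth_hist: dict[int, int] = {}
    if fpkm is not None:
        for gid in sequences:
            b = expression_breadth(fpkm.get(gid, {}), min_fpkm)
            breadth_hist[b] = breadth_hist.get(b, 0) + 1
        breadth_hist = dict(sorted(breadth_hist.items()))
    return GeneSetSummary(
        n_genes=n,
        tier_counts=tier_counts,
        tier_fractions=tier_fractions,
        gc_histogram=_histogram(gcs, gc_step),
        cds_length_histogram=_histogram(lengths_kb, cds_step_kb),
        expression_breadth_histogram=breadth_hist,
        gc_excluded=excluded,
    )


def compare_distributions(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (normal approximation, tie-corrected).

    Returns (statistic, p_value); identical samples give p = 1.0.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("rank-sum comparison requires two non-empty samples")
    if len(set(sample_a) | set(sample_b)) == 1:
        # every observation tied: zero rank variance, no evidence of a shift
        return float(len(sample_a) * len(sample_b) / 2.0), 1.0
    res = stats.mannwhitneyu(
        sample_a, sample_b, alternative="two-sided",
        method="asymptotic", use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)
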