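"""Peptide-spectrum-match filtering and proteomic validation percentages.

SEQUEST-style identifications are accepted when the preliminary score Sp is
at least 500, the preliminary rank RSp is at most 5, and the
cross-correlation XCorr clears a charge-dependent floor (1.5 / 2.0 / 2.5 /
3.0 for charges 1-4). A gene counts as proteomically validated when at
least two distinct peptide sequences among its passing hits support it
(pooled across tissues by default). The validation percentage of a gene
group is 100 * validated / expressed, reported to two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PeptideFilterParams",
    "ValidationSummary",
    "filter_peptide_hits",
    "validated_genes",
    "validation_percentage",
    "summarize_validation",
]

XCORR_FLOORS = {1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}

HIT_COLUMNS = ["gene_id", "peptide_sequence", "tissue",
               "sp_score", "rsp_rank", "xcorr", "charge"]


@dataclass(frozen=True)
class PeptideFilterParams:
    min_sp: float = 500.0
    max_rsp: int = 5
    xcorr_floors: Mapping[int, float] = None  # type: ignore[assignment]
    min_distinct_peptides: int = 2

    def __post_init__(self) -> None:
        if self.xcorr_floors is None:
            object.__setattr__(self, "xcorr_floors", dict(XCORR_FLOORS))


@dataclass(frozen=True)
class ValidationSummary:
    group: str
    genes_with_hits: int
    genes_expressed: int
    percent: float


def filter_peptide_hits(
    hits: pd.DataFrame, params: PeptideFilterParams = PeptideFilterParams()
) -> pd.DataFrame:
    """Keep hits with Sp >= 500, RSp <= 5 and XCorr >= the charge floor.

    Hits with a charge outside the calibrated 1-4 range are rejected with a
    warning rather than erroring out the batch.
    """
    bad_charge = ~hits["charge"].isin(params.xcorr_floors)
    if bad_charge.any():
        warnings.warn(
            f"{int(bad_charge.sum())} peptide hits with charge outside "
            f"{sorted(params.xcorr_floors)} rejected"
        )
    valid = hits[~bad_charge]
    floors = valid["charge"].map(params.xcorr_floors)
    keep = (
        (valid["sp_score"] >= params.min_sp)
        & (valid["rsp_rank"] <= params.max_rsp)
        & (valid["xcorr"] >= floors)
    )
    return valid[keep]


def validated_genes(
    passing_hits: pd.DataFrame,
    params: PeptideFilterParams = PeptideFilterParams(),
    per_tissue: bool = False,
) -> set[str]:
    """Genes with >= 2 distinct peptide sequences among their passing hits.

    Distinctness is exact sequence inequality. By default peptides are
    pooled across tissues; with ``per_tissue=True`` the requirement must be
    met within a single tissue.
    """
    if passing_hits.empty:
        return set()
    keys = ["gene_id", "tissue"] if per_tissue else ["gene_id"]
    counts = passing_hits.groupby(keys)["peptide_sequence"].nunique()
    ok = counts[counts >= params.min_distinct_peptides]
    if per_tissue:
        return set(ok.index.get_level_values("gene_id"))
    return set(ok.index)


def validation_percentage(validated: int, expressed: int) -> float:
    """100 * validated / expressed, to two decimals; expressed must be > 0."""
    if expressed <= 0:
        raise ValueError("validation percentage undefined for 0 expressed genes")
    if validated > expressed:
        raise ValueError("validated gene count exceeds expressed gene count")
    return round(100.0 * validated / expressed, 2)


def summarize_validation(
    hits: pd.DataFrame,
    expressed_by_group: Mapping[str, Iterable[str]],
    params: PeptideFilterParams = PeptideFilterParams(),
    per_tissue: bool = False,
) -> list[ValidationSummary]:
    """Per-group validation table plus a Total row over all groups.

    Only genes expressed in the proteome-assayed tissues participate; hits
    to genes outside a group's expressed set are ignored for that group.
    """
    passing = filter_peptide_hits(hits, params)
    validated = validated_genes(passing, params, per_tissue)
    rows: list[ValidationSummary] = []
    all_expressed: set[str] = set()
    all_validated: set[str] = set()
    for group, genes in expressed_by_group.items():
        genes = set(genes)
        hit_genes = validated & genes
        rows.append(
            ValidationSummary(
                group=group,
                genes_with_hits=len(hit_genes),
                genes_expressed=len(genes),
                percent=validation_percentage(len(hit_genes), len(genes)),
            )
        )
        all_expressed |= genes
        all_validated |= hit_genes
    rows.append(
        ValidationSummary(
            group="Total",
            genes_with_hits=len(all_validated),
            genes_expressed=len(all_expressed),
            percent=validation_percentage(len(all_validated), len(all_expressed)),
        )
    )
    return rows
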