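"""Synthetic fixture generator with a machine-readable planted truth ledger.

Builds a small "true" genome, derives a deliberately damaged draft from it
by planting typed assembly defects, and emits every input the pipeline
consumes — transcripts, PSL alignments, gene-model and abundance GTFs,
repeat BED, homology/ncRNA evidence tables, a peptide-spectrum-match table
and QC-test reads — together with a ledger of every planted event and gene
so downstream recovery can be scored exactly.

Planted defect kinds and the evidence transcripts that expose them:

* ``join``   — a true scaffold split in two; a transcript spans the break.
* ``merge``  — an interior block excised into its own small scaffold and
  replaced by an equally long N-run; a transcript crosses host-insert-host.
* ``strand_inconsistency`` — an interior block reverse-complemented.
* ``nest``   — one copy of a true tandem duplication collapsed.
* ``boundary_extension`` — a scaffold end truncated; a transcript hangs off.
* ``gap_fill`` — an interior block replaced by an N-run whose length
  mis-estimates the truth for a configurable fraction of gaps.

Evidence tables (nr/nt/dbEST hits, peptides) are generated directly from
the planted tier assignments with values strictly clear of the decision
thresholds, rather than by running search tools.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import psl as pslmod
from .gtfio import GtfTranscript, write_gtf, write_bed
from .orfhomology import HomologyHit, OrfRecord
from .readqc import Read, write_fastq
from .txalign import AlignmentSegment, ImprovementCall, revcomp

__all__ = [
    "FixtureConfig",
    "PlantedTruth",
    "Fixture",
    "generate_fixture",
    "score_recovery",
    "align_exact",
]

FLANK = 300  # aligned transcript flank on each side of a planted defect
BASES = np.array(list("ACGT"))
AA = list("ACDEFGHIKLMNPQRSTVWY")
STOP_FREE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

TIERS = ("homology_based", "unknown", "hypothetical")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Defaults give >= 20 planted events per defect kind on ~6 kb scaffolds
    (about 1 Mb of genome), a gap-length mis-estimation rate that leaves
    ~6.6% of gaps exactly sized, a three-tier novel-gene mix matching the
    observed 551 : 6,290 : 12,575 proportions, and a ~12.6% proteomic
    validation rate.
    """

    seed: int = 0
    genome_length: int = 1_080_000
    n_scaffolds: int = 180
    n_join_events: int = 20
    n_merge_events: int = 20
    n_inversion_events: int = 20
    n_nest_events: int = 20
    n_boundary_truncations: int = 20
    n_gaps: int = 20
    gap_len_range: tuple[int, int] = (50, 300)
    gap_predicted_error: float = 0.9336  # fraction of N-runs mis-sized
    n_true_genes: int = 20
    n_novel_genes: int = 60
    tier_mix: tuple[float, float, float] = (0.0284, 0.3240, 0.6476)
    full_length_fraction: float = 0.6805  # complete-ORF share of candidates
    fpkm_lognormal_params: tuple[float, float] = (0.5, 1.2)  # mu, sigma of ln FPKM
    peptide_hit_rate: float = 0.1262
    n_tissues: int = 12
    n_proteome_tissues: int = 5
    n_read_pairs: int = 120
    read_length: int = 101
    n_unaligned_transcripts: int = 12

    @property
    def scaffold_length(self) -> int:
        return self.genome_length // self.n_scaffolds

    @property
    def event_counts(self) -> dict[str, int]:
        return {
            "join": self.n_join_events,
            "merge": self.n_merge_events,
            "strand_inconsistency": self.n_inversion_events,
            "nest": self.n_nest_events,
            "boundary_extension": self.n_boundary_truncations,
            "gap_fill": self.n_gaps,
        }

    def validate(self) -> None:
        counts = list(self.event_counts.values()) + [
            self.n_true_genes, self.n_novel_genes, self.n_read_pairs,
            self.n_unaligned_transcripts,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if abs(sum(self.tier_mix) - 1.0) > 1e-9:
            raise ValueError(f"tier_mix must sum to 1, got {sum(self.tier_mix)}")
        if not 0.0 <= self.gap_predicted_error <= 1.0:
            raise ValueError("gap_predicted_error must be a fraction in [0,1]")
        if not 0.0 <= self.peptide_hit_rate <= 1.0:
            raise ValueError("peptide_hit_rate must be a fraction in [0,1]")
        if self.gap_len_range[0] < 10 or self.gap_len_range[0] > self.gap_len_range[1]:
            raise ValueError("gap_len_range must be an interval with lower bound >= 10")
        sl = self.scaffold_length
        if sl < 4800:
            raise ValueError(
                f"scaffold length genome_length//n_scaffolds = {sl} too short; "
                "events and gene loci need scaffolds of >= 4800 bp"
            )
        needed = self._scaffolds_needed()
        if needed > self.n_scaffolds:
            raise ValueError(
                f"impossible config: {needed} scaffolds needed to host all "
                f"events and genes, but n_scaffolds = {self.n_scaffolds}"
            )

    def _genes_per_scaffold(self) -> int:
        return max(1, (self.scaffold_length - 600) // 1800)

    def _scaffolds_needed(self) -> int:
        gps = self._genes_per_scaffold()
        n_events = sum(self.event_counts.values())
        n_known = -(-self.n_true_genes // 2) if self.n_true_genes else 0
        n_novel = -(-self.n_novel_genes // gps) if self.n_novel_genes else 0
        return n_events + n_known + n_novel + 1  # +1 aux (repeat/noise) scaffold


@dataclass
class PlantedTruth:
    """Ledger of everything the generator planted."""

    events: list[dict] = field(default_factory=list)
    novel_genes: list[dict] = field(default_factory=list)
    qc_labels: dict[str, list[int]] = field(default_factory=dict)
    aux: dict = field(default_factory=dict)

    def events_of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]

    def to_json(self) -> str:
        return json.dumps(
            {"events": self.events, "novel_genes": self.novel_genes,
             "qc_labels": self.qc_labels, "aux": self.aux},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(d["events"], d["novel_genes"], d["qc_labels"], d.get("aux", {}))


@dataclass
class Fixture:
    config: FixtureConfig
    true_genome: dict[str, str]
    draft_genome: dict[str, str]
    transcripts: dict[str, str]          # aligned, de novo style
    unaligned_transcripts: dict[str, str]
    psl_records: list
    gene_models: list[GtfTranscript]
    abundance: list[GtfTranscript]       # reference-based assemblies w/ FPKM
    repeats: dict[str, list[tuple[int, int]]]
    orfs: dict[str, OrfRecord]
    homology_hits: list[HomologyHit]
    ncrna_hits: list[dict]
    peptide_hits: pd.DataFrame
    read_pairs: list[tuple[Read, Read]]
    truth: PlantedTruth

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.config.n_tissues)]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artefact as plain text; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _fasta(name: str, seqs: Mapping[str, str]) -> None:
            p = outdir / name
            with open(p, "w") as fh:
                for sid in sorted(seqs):
                    fh.write(f">{sid}\n")
                    s = seqs[sid]
                    for i in range(0, len(s), 80):
                        fh.write(s[i: i + 80] + "\n")
            paths[name] = p

        _fasta("true_genome.fa", self.true_genome)
        _fasta("draft_genome.fa", self.draft_genome)
        _fasta("transcripts.fa", {**self.transcripts, **self.unaligned_transcripts})
        with open(outdir / "alignments.psl", "w") as fh:
            pslmod.write_psl(self.psl_records, fh)
        paths["alignments.psl"] = outdir / "alignments.psl"
        with open(outdir / "gene_models.gtf", "w") as fh:
            write_gtf(self.gene_models, fh)
        paths["gene_models.gtf"] = outdir / "gene_models.gtf"
        with open(outdir / "abundance.gtf", "w") as fh:
            write_gtf(self.abundance, fh)
        paths["abundance.gtf"] = outdir / "abundance.gtf"
        with open(outdir / "repeat_mask.bed", "w") as fh:
            write_bed(self.repeats, fh)
        paths["repeat_mask.bed"] = outdir / "repeat_mask.bed"

        orf_rows = [
            {"transcript_id": o.transcript_id, "cds_start": o.cds_start,
             "cds_end": o.cds_end, "strand": o.strand,
             "has_start_codon": o.has_start_codon,
             "has_stop_codon": o.has_stop_codon}
            for o in self.orfs.values()
        ]
        pd.DataFrame(orf_rows).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
        paths["orfs.tsv"] = outdir / "orfs.tsv"

        hit_rows = [
            {"query_id": h.query_id, "database": h.database, "evalue": h.evalue,
             "target_id": h.target_id, "target_length": h.target_length,
             "align_start": h.align_start, "align_end": h.align_end,
             "gap_size": h.gap_size}
            for h in self.homology_hits
        ]
        pd.DataFrame(
            hit_rows,
            columns=["query_id", "database", "evalue", "target_id",
                     "target_length", "align_start", "align_end", "gap_size"],
        ).to_csv(outdir / "homology_hits.tsv", sep="\t", index=False)
        paths["homology_hits.tsv"] = outdir / "homology_hits.tsv"

        pd.DataFrame(
            self.ncrna_hits, columns=["transcript_id", "target_id", "evalue"]
        ).to_csv(outdir / "ncrna_hits.tsv", sep="\t", index=False)
        paths["ncrna_hits.tsv"] = outdir / "ncrna_hits.tsv"

        self.peptide_hits.to_csv(outdir / "peptide_hits.tsv", sep="\t", index=False)
        paths["peptide_hits.tsv"] = outdir / "peptide_hits.tsv"

        with open(outdir / "reads_1.fastq", "w") as fh:
            write_fastq((p[0] for p in self.read_pairs), fh)
        with open(outdir / "reads_2.fastq", "w") as fh:
            write_fastq((p[1] for p in self.read_pairs), fh)
        paths["reads_1.fastq"] = outdir / "reads_1.fastq"
        paths["reads_2.fastq"] = outdir / "reads_2.fastq"

        with open(outdir / "truth.json", "w") as fh:
            fh.write(self.truth.to_json())
        paths["truth.json"] = outdir / "truth.json"
        return paths

    def checksums(self) -> dict[str, str]:
        """Stable content digests of every artefact (determinism checks)."""
        sums = {}
        buf = io.StringIO()
        pslmod.write_psl(self.psl_records, buf)
        sums["alignments.psl"] = hashlib.sha256(buf.getvalue().encode()).hexdigest()
        for name, seqs in (
            ("true_genome.fa", self.true_genome),
            ("draft_genome.fa", self.draft_genome),
            ("transcripts.fa", self.transcripts),
        ):
            text = "".join(f">{k}\n{v}\n" for k, v in sorted(seqs.items()))
            sums[name] = hashlib.sha256(text.encode()).hexdigest()
        sums["truth.json"] = hashlib.sha256(self.truth.to_json().encode()).hexdigest()
        sums["peptide_hits.tsv"] = hashlib.sha256(
            self.peptide_hits.to_csv(sep="\t", index=False).encode()
        ).hexdigest()
        return sums


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _apportion(total: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of `total` over `proportions`."""
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: -(raw[i] - counts[i]))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _single_block_record(
    tid: str, tlen: int, scaffold: str, slen: int, strand: str,
    q_start: int, g_start: int, size: int,
):
    return pslmod.make_record(
        tid, tlen, scaffold, slen, strand, [(q_start, g_start)], [size]
    )


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Deterministically build a fixture from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sl = config.scaffold_length
    tissues = [f"tissue{i:02d}" for i in range(config.n_tissues)]

    true_genome: dict[str, str] = {}
    draft: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    records: list = []
    truth = PlantedTruth()

    scaffold_idx = 0

    def next_sid() -> str:
        nonlocal scaffold_idx
        sid = f"scaf{scaffold_idx:04d}"
        scaffold_idx += 1
        return sid

    # ---- planted assembly defects, one scaffold each --------------------
    for ev_i in range(config.n_join_events):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        m = sl // 2
        a_id, b_id = f"{sid}_a", f"{sid}_b"
        draft[a_id] = s[:m]
        draft[b_id] = s[m:]
        tid = f"tx_join_{ev_i:03d}"
        region = s[m - FLANK: m + FLANK]
        if ev_i % 2 == 0:  # forward-orientation evidence
            transcripts[tid] = region
            records.append(_single_block_record(tid, 2 * FLANK, a_id, m, "+",
                                                0, m - FLANK, FLANK))
            records.append(_single_block_record(tid, 2 * FLANK, b_id, sl - m, "+",
                                                FLANK, 0, FLANK))
            pattern = "++"
        else:  # the transcript assembled in the reverse orientation
            transcripts[tid] = revcomp(region)
            records.append(_single_block_record(tid, 2 * FLANK, a_id, m, "-",
                                                FLANK, m - FLANK, FLANK))
            records.append(_single_block_record(tid, 2 * FLANK, b_id, sl - m, "-",
                                                0, 0, FLANK))
            pattern = "--"
        truth.events.append(
            {"kind": "join", "scaffolds": [a_id, b_id], "coordinates": [m, 0],
             "pattern": pattern, "transcript": tid}
        )

    for ev_i in range(config.n_merge_events):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        ilen = int(rng.integers(200, 401))
        a = sl // 2 - ilen // 2
        b = a + ilen
        m_id = f"{sid}_m"
        draft[sid] = s[:a] + "N" * ilen + s[b:]
        draft[m_id] = s[a:b]
        tid = f"tx_merge_{ev_i:03d}"
        tlen = 2 * FLANK + ilen
        transcripts[tid] = s[a - FLANK: b + FLANK]
        records.append(_single_block_record(tid, tlen, sid, sl, "+",
                                            0, a - FLANK, FLANK))
        records.append(_single_block_record(tid, tlen, m_id, ilen, "+",
                                            FLANK, 0, ilen))
        records.append(_single_block_record(tid, tlen, sid, sl, "+",
                                            FLANK + ilen, a + ilen, FLANK))
        truth.events.append(
            {"kind": "merge", "scaffolds": [sid, m_id],
             "coordinates": [a, a + ilen], "transcript": tid}
        )

    for ev_i in range(config.n_inversion_events):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        ilen = int(rng.integers(150, 301))
        a = sl // 2
        b = a + ilen
        draft[sid] = s[:a] + revcomp(s[a:b]) + s[b:]
        tid = f"tx_inv_{ev_i:03d}"
        tlen = 2 * FLANK + ilen
        transcripts[tid] = s[a - FLANK: b + FLANK]
        records.append(_single_block_record(tid, tlen, sid, sl, "+",
                                            0, a - FLANK, FLANK))
        records.append(_single_block_record(tid, tlen, sid, sl, "-",
                                            FLANK, a, ilen))
        records.append(_single_block_record(tid, tlen, sid, sl, "+",
                                            FLANK + ilen, b, FLANK))
        truth.events.append(
            {"kind": "strand_inconsistency", "scaffolds": [sid],
             "coordinates": [a, b], "transcript": tid}
        )

    for ev_i in range(config.n_nest_events):
        sid = next_sid()
        r = int(rng.integers(150, 251))
        w = _rand_seq(rng, sl - r)
        a = sl // 2
        unit = w[a: a + r]
        true_genome[sid] = w[:a] + unit + w[a:]  # tandem duplication of `unit`
        draft[sid] = w  # draft collapsed one copy
        tid = f"tx_nest_{ev_i:03d}"
        tlen = 2 * FLANK + 2 * r
        transcripts[tid] = true_genome[sid][a - FLANK: a + 2 * r + FLANK]
        records.append(_single_block_record(tid, tlen, sid, sl - r, "+",
                                            0, a - FLANK, FLANK + r))
        records.append(_single_block_record(tid, tlen, sid, sl - r, "+",
                                            FLANK + r, a, r + FLANK))
        truth.events.append(
            {"kind": "nest", "scaffolds": [sid], "coordinates": [a, a + r],
             "overlap": r, "transcript": tid}
        )

    for ev_i in range(config.n_boundary_truncations):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        t = int(rng.integers(80, 201))
        tid = f"tx_ext_{ev_i:03d}"
        tlen = FLANK + t
        if ev_i % 2 == 0:  # truncate the right scaffold end
            draft[sid] = s[: sl - t]
            transcripts[tid] = s[sl - t - FLANK:]
            records.append(_single_block_record(tid, tlen, sid, sl - t, "+",
                                                0, sl - t - FLANK, FLANK))
            truth.events.append(
                {"kind": "boundary_extension", "scaffolds": [sid],
                 "coordinates": [sl - t], "side": "right", "length": t,
                 "transcript": tid}
            )
        else:  # truncate the left scaffold end
            draft[sid] = s[t:]
            transcripts[tid] = s[: t + FLANK]
            records.append(_single_block_record(tid, tlen, sid, sl - t, "+",
                                                t, 0, FLANK))
            truth.events.append(
                {"kind": "boundary_extension", "scaffolds": [sid],
                 "coordinates": [0], "side": "left", "length": t,
                 "transcript": tid}
            )

    n_exact_gaps = 0
    for ev_i in range(config.n_gaps):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        glen = int(rng.integers(config.gap_len_range[0], config.gap_len_range[1] + 1))
        if rng.random() < config.gap_predicted_error:
            delta = int(rng.integers(10, 51)) * (1 if rng.random() < 0.5 else -1)
            delta = max(delta, 10 - glen)  # keep the N-run a real gap
            n_len = glen + delta
        else:
            n_len = glen
            n_exact_gaps += 1
        a = sl // 2 - glen // 2
        b = a + glen
        draft[sid] = s[:a] + "N" * n_len + s[b:]
        tid = f"tx_gap_{ev_i:03d}"
        tlen = 2 * FLANK + glen
        transcripts[tid] = s[a - FLANK: b + FLANK]
        records.append(_single_block_record(tid, tlen, sid, len(draft[sid]), "+",
                                            0, a - FLANK, FLANK))
        records.append(_single_block_record(tid, tlen, sid, len(draft[sid]), "+",
                                            FLANK + glen, a + n_len, FLANK))
        truth.events.append(
            {"kind": "gap_fill", "scaffolds": [sid],
             "coordinates": [a, a + n_len], "filled_length": glen,
             "predicted_gap_length": n_len, "exact_match": glen == n_len,
             "transcript": tid}
        )
    truth.aux["n_exact_gaps"] = n_exact_gaps

    # ---- known gene models (2 per scaffold) ------------------------------
    gene_models: list[GtfTranscript] = []
    abundance: list[GtfTranscript] = []
    known_templates = [
        ((500, 800), (1200, 1500), "+"),
        ((3500, 3800), (4200, 4500), "-"),
    ]
    n_known_scaffolds = -(-config.n_true_genes // 2) if config.n_true_genes else 0
    known_sids: list[str] = []
    gi = 0
    for _ in range(n_known_scaffolds):
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        draft[sid] = s
        known_sids.append(sid)
        for ex1, ex2, strand in known_templates:
            if gi >= config.n_true_genes:
                break
            gid = f"known_g{gi:04d}"
            gene_models.append(
                GtfTranscript(gid + ".t1", gid, sid, strand, [list(ex1), list(ex2)])
            )
            gi += 1

    # classification-exercise transcripts on the first known scaffold
    if known_sids and config.n_true_genes:
        sid = known_sids[0]
        s = draft[sid]
        # exact intron-chain match of the '+' model
        tid = "tx_known_match"
        seq = s[500:800] + s[1200:1500]
        transcripts[tid] = seq
        records.append(
            pslmod.make_record(tid, len(seq), sid, sl, "+",
                               [(0, 500), (300, 1200)], [300, 300])
        )
        # mono-exon same-strand overlap of the '+' model
        tid = "tx_known_overlap"
        transcripts[tid] = s[700:1000]
        records.append(_single_block_record(tid, 300, sid, sl, "+", 0, 700, 300))
        if config.n_true_genes > 1:
            # antisense of the '-' model, aligned on '+'
            tid = "tx_antisense"
            transcripts[tid] = s[3600:3900]
            records.append(_single_block_record(tid, 300, sid, sl, "+", 0, 3600, 300))
        truth.aux["classification_controls"] = {
            "tx_known_match": "match",
            "tx_known_overlap": "overlap_known",
            **({"tx_antisense": "antisense_novel"} if config.n_true_genes > 1 else {}),
        }

    # ---- novel genes ------------------------------------------------------
    n_full = round(config.full_length_fraction * config.n_novel_genes)
    tier_counts = _apportion(n_full, config.tier_mix)
    verdicts: list[tuple[str, str | None]] = []
    for tier, cnt in zip(TIERS, tier_counts):
        verdicts += [("full_length", tier)] * cnt
    for j in range(config.n_novel_genes - n_full):
        verdicts.append(("rejected_partial" if j % 2 == 0 else "rejected_small", None))
    order = rng.permutation(len(verdicts))
    verdicts = [verdicts[i] for i in order]

    gps = config._genes_per_scaffold()
    orfs: dict[str, OrfRecord] = {}
    homology_hits: list[HomologyHit] = []
    novel_sids: list[str] = []
    slot = gps  # force allocation on first gene
    sid = ""
    s_list: list[str] = []

    def flush_novel_scaffold() -> None:
        if sid:
            seq = "".join(s_list)
            seq = seq + _rand_seq(rng, sl - len(seq))
            true_genome[sid] = seq
            draft[sid] = seq

    for g_i, (verdict, tier) in enumerate(verdicts):
        if slot >= gps:
            flush_novel_scaffold()
            sid = next_sid()
            novel_sids.append(sid)
            s_list = []
            slot = 0
        gid = f"novel_g{g_i:04d}"
        tid = f"tx_{gid}"
        offset = 300 + slot * 1800
        utr5 = int(rng.integers(60, 121))
        if verdict == "full_length":
            n_codons = int(rng.integers(100, 200))
            cds = "ATG" + "".join(
                STOP_FREE_CODONS[i] for i in rng.integers(0, 61, size=n_codons)
            ) + "TAA"
            utr3 = int(rng.integers(60, 121))
            mrna = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
            orf = OrfRecord(tid, utr5, utr5 + len(cds), "+", True, True)
        elif verdict == "rejected_partial":
            n_codons = int(rng.integers(100, 160))
            cds = "ATG" + "".join(
                STOP_FREE_CODONS[i] for i in rng.integers(0, 61, size=n_codons)
            )
            mrna = _rand_seq(rng, utr5) + cds  # runs off the 3' end, no stop
            orf = OrfRecord(tid, utr5, utr5 + len(cds), "+", True, False)
        else:  # rejected_small: complete ORF at exactly the 150 bp bound
            n_codons = 48
            cds = "ATG" + "".join(
                STOP_FREE_CODONS[i] for i in rng.integers(0, 61, size=n_codons)
            ) + "TAA"
            assert len(cds) == 150
            utr3 = int(rng.integers(60, 121))
            mrna = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
            orf = OrfRecord(tid, utr5, utr5 + len(cds), "+", True, True)
        orfs[tid] = orf

        # plant the gene into the scaffold under construction
        pad = offset - sum(len(x) for x in s_list)
        s_list.append(_rand_seq(rng, pad))
        s_list.append(mrna)
        start, end = offset, offset + len(mrna)
        strand = "+" if g_i % 2 == 0 else "-"
        transcripts[tid] = mrna if strand == "+" else mrna  # transcript is sense
        if strand == "+":
            records.append(_single_block_record(tid, len(mrna), sid, sl, "+",
                                                0, start, len(mrna)))
        else:
            # genomic locus holds the reverse complement of the mRNA
            s_list[-1] = revcomp(mrna)
            records.append(_single_block_record(tid, len(mrna), sid, sl, "-",
                                                0, start, len(mrna)))
        slot += 1

        # reference-based (pooled-assembly) twin, 20 bp shorter on each side
        fpkm = {
            t: float(np.round(rng.lognormal(*config.fpkm_lognormal_params), 3))
            for t in tissues
        }
        if max(fpkm.values()) < 1.0:
            fpkm[tissues[int(rng.integers(0, len(tissues)))]] = float(
                np.round(rng.uniform(2.0, 8.0), 3)
            )
        expressed = sorted(t for t, v in fpkm.items() if v >= 1.0)
        abundance.append(
            GtfTranscript(
                f"cuff_{gid}", f"cuff_{gid}", sid, strand,
                [(start + 20, end - 20)],
                {f"FPKM_{t}": f"{v}" for t, v in fpkm.items()},
            )
        )

        # homology evidence planted from the tier assignment
        if tier == "homology_based":
            tl = int(rng.integers(120, 220))
            cov_end = int(np.ceil(0.96 * tl)) + int(rng.integers(0, tl - int(np.ceil(0.96 * tl)) + 1))
            homology_hits.append(HomologyHit(
                tid, "nr", float(10.0 ** -rng.integers(8, 40)),
                f"nr_{gid}", tl, 0, cov_end, 0))
            if rng.random() < 0.5:  # sometimes cDNA support too
                tl2 = int(rng.integers(300, 900))
                homology_hits.append(HomologyHit(
                    tid, "nt", float(10.0 ** -rng.integers(8, 40)),
                    f"nt_{gid}", tl2, 0, int(np.ceil(0.97 * tl2)), 0))
        elif tier == "unknown":
            tl = int(rng.integers(300, 900))
            homology_hits.append(HomologyHit(
                tid, "dbEST", float(10.0 ** -rng.integers(8, 30)),
                f"est_{gid}", tl, 0, int(np.ceil(0.97 * tl)), 0))
            # sub-threshold protein hit: e-value too weak
            homology_hits.append(HomologyHit(
                tid, "nr", 1e-3, f"nr_{gid}", 150, 0, 148, 0))
        elif tier == "hypothetical":
            choice = rng.random()
            if choice < 0.4:  # alignment too short (9 aa < 10)
                homology_hits.append(HomologyHit(
                    tid, "nr", 1e-10, f"nr_{gid}", 150, 0, 9, 0))
            elif choice < 0.7:  # coverage far below 95%
                tl = int(rng.integers(300, 900))
                homology_hits.append(HomologyHit(
                    tid, "nt", 1e-12, f"nt_{gid}", tl, 0, int(0.60 * tl), 0))
            # else: no hits at all
        truth.novel_genes.append(
            {"id": gid, "transcript": tid, "tier": tier,
             "full_length": verdict == "full_length", "verdict": verdict,
             "scaffold": sid, "span": [start, end], "strand": strand,
             "cds": [orf.cds_start, orf.cds_end],
             "expressed_tissues": expressed,
             "fpkm": fpkm}
        )
    flush_novel_scaffold()

    # ---- aux scaffold: repeat-masked and low-abundance decoys -------------
    aux_sid = next_sid()
    aux_seq = _rand_seq(rng, sl)
    true_genome[aux_sid] = aux_seq
    draft[aux_sid] = aux_seq
    repeats: dict[str, list[tuple[int, int]]] = {aux_sid: []}
    repeat_controls = []
    for j, offset in enumerate((300, 1300, 2300)):
        tid = f"tx_repeat_{j}"
        transcripts[tid] = aux_seq[offset: offset + 400]
        records.append(_single_block_record(tid, 400, aux_sid, sl, "+",
                                            0, offset, 400))
        repeats[aux_sid].append((offset, offset + 240))  # 60% of the exon
        repeat_controls.append(tid)
    noise_ids = []
    for j, offset in enumerate((3300, 3800, 4300)):
        ntid = f"cuff_noise_{j}"
        abundance.append(
            GtfTranscript(
                ntid, ntid, aux_sid, "+", [(offset, offset + 300)],
                {f"FPKM_{t}": f"{np.round(rng.uniform(0.05, 0.95), 3)}"
                 for t in tissues},
            )
        )
        noise_ids.append(ntid)
    truth.aux["repeat_rejected"] = repeat_controls
    truth.aux["low_abundance"] = noise_ids

    # leftover plain scaffolds up to n_scaffolds
    while scaffold_idx < config.n_scaffolds:
        sid = next_sid()
        s = _rand_seq(rng, sl)
        true_genome[sid] = s
        draft[sid] = s

    # ---- unaligned (reference-free) transcripts --------------------------
    unaligned: dict[str, str] = {}
    n_un = config.n_unaligned_transcripts
    n_clusters = max(n_un // 2, 1) if n_un else 0
    cluster_map: dict[str, list[str]] = {}
    k = 0
    for c in range(n_clusters):
        if k >= n_un:
            break
        base = _rand_seq(rng, int(rng.integers(400, 900)))
        tid = f"tx_un_{k:03d}"
        unaligned[tid] = base
        members = [tid]
        k += 1
        if k < n_un and (c % 2 == 0 or n_clusters * 2 <= n_un):
            tid2 = f"tx_un_{k:03d}"
            unaligned[tid2] = base[20:-20]  # exact substring: same cluster
            members.append(tid2)
            k += 1
        cluster_map[members[0]] = members
    while k < n_un:
        tid = f"tx_un_{k:03d}"
        unaligned[tid] = _rand_seq(rng, int(rng.integers(400, 900)))
        cluster_map[tid] = [tid]
        k += 1
    reps = sorted(cluster_map)
    ncrna_hits = [
        {"transcript_id": rep, "target_id": f"ncRNA_{i}", "evalue": 1e-20}
        for i, rep in enumerate(reps[:2])
    ]
    truth.aux["unaligned_clusters"] = {r: sorted(m) for r, m in cluster_map.items()}
    truth.aux["ncrna_removed"] = [h["transcript_id"] for h in ncrna_hits]

    # ---- peptide-spectrum matches -----------------------------------------
    proteome_tissues = tissues[: config.n_proteome_tissues]
    pep_rows = []

    def rand_peptide() -> str:
        return "".join(AA[i] for i in rng.integers(0, 20, size=int(rng.integers(8, 16))))

    for g in truth.novel_genes:
        expressed5 = [t for t in g["expressed_tissues"] if t in proteome_tissues]
        g["expressed_in_proteome_tissues"] = bool(expressed5)
        g["validated"] = False
        if g["verdict"] != "full_length" or not expressed5:
            continue
        if rng.random() < config.peptide_hit_rate:
            g["validated"] = True
            for _ in range(int(rng.integers(2, 4))):
                pep_rows.append({
                    "gene_id": g["id"], "peptide_sequence": rand_peptide(),
                    "tissue": expressed5[int(rng.integers(0, len(expressed5)))],
                    "sp_score": float(np.round(rng.uniform(520, 1500), 1)),
                    "rsp_rank": int(rng.integers(1, 6)),
                    "charge": int(rng.integers(1, 5)),
                })
        else:
            decoy = rng.random()
            if decoy < 0.3:  # one passing peptide only: below distinctness bar
                pep_rows.append({
                    "gene_id": g["id"], "peptide_sequence": rand_peptide(),
                    "tissue": expressed5[0],
                    "sp_score": float(np.round(rng.uniform(520, 1500), 1)),
                    "rsp_rank": int(rng.integers(1, 6)),
                    "charge": int(rng.integers(1, 5)),
                })
            elif decoy < 0.6:  # two peptides failing the score filters
                for fail_mode in ("sp", "xcorr"):
                    row = {
                        "gene_id": g["id"], "peptide_sequence": rand_peptide(),
                        "tissue": expressed5[0],
                        "sp_score": float(np.round(rng.uniform(520, 1500), 1)),
                        "rsp_rank": int(rng.integers(1, 6)),
                        "charge": int(rng.integers(1, 5)),
                    }
                    if fail_mode == "sp":
                        row["sp_score"] = float(np.round(rng.uniform(100, 499), 1))
                    else:
                        row["charge"] = 4
                        row["xcorr"] = float(np.round(rng.uniform(1.0, 2.9), 2))
                    pep_rows.append(row)
    for row in pep_rows:
        if "xcorr" not in row:
            floor = {1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}[row["charge"]]
            row["xcorr"] = float(np.round(floor + rng.uniform(0.0, 2.0), 2))
    peptide_hits = pd.DataFrame(
        pep_rows,
        columns=["gene_id", "peptide_sequence", "tissue", "sp_score",
                 "rsp_rank", "xcorr", "charge"],
    )

    # ---- QC reads ----------------------------------------------------------
    read_pairs: list[tuple[Read, Read]] = []
    rl = config.read_length

    def make_read(rid: str, archetype: str) -> Read:
        seq = list(_rand_seq(rng, rl))
        if "N" in seq:
            seq = [b if b != "N" else "A" for b in seq]
        quals = [40] * rl
        failed: list[int] = []
        if archetype == "rule1":
            seq[int(rng.integers(0, 30))] = "N"
            failed = [1]
        elif archetype == "rule2":
            for p in rng.choice(rl, size=4, replace=False):
                quals[p] = 9
            failed = [2]
        elif archetype == "rule3":
            for p in rng.choice(rl, size=5, replace=False):
                quals[p] = 12
            failed = [3]
        elif archetype == "rule4":
            n_low = int(np.floor(0.60 * rl)) + 1
            for p in rng.choice(rl, size=n_low, replace=False):
                quals[p] = 19
            failed = [4]
        elif archetype == "rule5":
            # mean below 20 while <=60% of bases sit under quality 20,
            # so rule 4 stays silent and only the mean rule fires
            n_mid = int(np.floor(0.60 * rl))
            picks = set(rng.choice(rl, size=n_mid, replace=False).tolist())
            quals = [13 if p in picks else 25 for p in range(rl)]
            failed = [5]
        elif archetype == "rule23":
            for p in rng.choice(rl, size=5, replace=False):
                quals[p] = 9
            failed = [2, 3]
        truth.qc_labels[rid] = sorted(failed)
        return Read(rid, "".join(seq), tuple(quals))

    archetypes = ["clean", "rule1", "rule2", "rule3", "rule4", "rule5", "rule23"]
    for i in range(config.n_read_pairs):
        pick = rng.random(2)
        arch = [
            "clean" if p < 0.7 else archetypes[1 + int(rng.integers(0, 6))]
            for p in pick
        ]
        r1 = make_read(f"read{i:05d}/1", arch[0])
        r2 = make_read(f"read{i:05d}/2", arch[1])
        read_pairs.append((r1, r2))

    return Fixture(
        config=config,
        true_genome=true_genome,
        draft_genome=draft,
        transcripts=transcripts,
        unaligned_transcripts=unaligned,
        psl_records=records,
        gene_models=gene_models,
        abundance=abundance,
        repeats=repeats,
        orfs=orfs,
        homology_hits=homology_hits,
        ncrna_hits=ncrna_hits,
        peptide_hits=peptide_hits,
        read_pairs=read_pairs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def _interval_close(a: Sequence[int], b: Sequence[int], tol: int) -> bool:
    return all(abs(x - y) <= tol for x, y in zip(a, b))


def _call_matches_event(call: ImprovementCall, event: dict, tol: int) -> bool:
    if call.kind != event["kind"]:
        return False
    if call.kind in ("join", "merge"):
        return set(call.scaffolds) == set(event["scaffolds"])
    if call.scaffolds[0] != event["scaffolds"][0]:
        return False
    if call.kind == "boundary_extension":
        return (
            call.details.get("side") == event["side"]
            and abs(call.coordinates[0] - event["coordinates"][0]) <= tol
        )
    if call.kind == "gap_fill":
        return _interval_close(call.coordinates, event["coordinates"], tol)
    if call.kind == "nest":
        return _interval_close(call.coordinates, event["coordinates"], tol)
    if call.kind == "strand_inconsistency":
        # any reported pair overlapping the inverted interval counts
        lo, hi = call.coordinates
        e_lo, e_hi = event["coordinates"]
        return lo < e_hi + tol and hi > e_lo - tol
    return False


def score_recovery(
    calls: Sequence[ImprovementCall], truth: PlantedTruth, tol: int = 10
) -> dict[str, dict[str, float | None]]:
    """Per-event-kind precision and recall of calls against the ledger.

    precision = matched calls / calls of that kind; recall = planted events
    matched by >= 1 call / planted events. With no planted events of a kind,
    recall is not applicable (None) and precision is 0.0 when spurious calls
    exist, 1.0 (vacuous) otherwise.
    """
    kinds = ("join", "merge", "strand_inconsistency", "nest",
             "boundary_extension", "gap_fill")
    out: dict[str, dict[str, float | None]] = {}
    for kind in kinds:
        kind_calls = [c for c in calls if c.kind == kind]
        events = truth.events_of_kind(kind)
        matched_calls = sum(
            any(_call_matches_event(c, e, tol) for e in events) for c in kind_calls
        )
        matched_events = sum(
            any(_call_matches_event(c, e, tol) for c in kind_calls) for e in events
        )
        if not events:
            out[kind] = {
                "precision": 1.0 if not kind_calls else 0.0,
                "recall": None,
                "n_calls": len(kind_calls),
                "n_events": 0,
            }
            continue
        out[kind] = {
            "precision": (matched_calls / len(kind_calls)) if kind_calls else 0.0,
            "recall": matched_events / len(events),
            "n_calls": len(kind_calls),
            "n_events": len(events),
        }
    return out


# ---------------------------------------------------------------------------
# exact re-alignment (for round-trip/idempotence checks on fixtures)
# ---------------------------------------------------------------------------

def align_exact(
    transcripts: Mapping[str, str],
    genome: Mapping[str, str],
    k: int = 24,
    min_seg: int = 40,
) -> list[AlignmentSegment]:
    """Seed-and-extend exact aligner over a k-mer index of the genome.

    Only suited to the noise-free fixtures here (exact substring matches, no
    mismatches); used to re-align transcripts to an edited genome without an
    external aligner.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for sid in sorted(genome):
        seq = genome[sid]
        for i in range(0, len(seq) - k + 1):
            kmer = seq[i: i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((sid, i))

    segments: list[AlignmentSegment] = []
    for tid in sorted(transcripts):
        tseq = transcripts[tid]
        tlen = len(tseq)
        seen: set[tuple] = set()
        for strand, seq in (("+", tseq), ("-", revcomp(tseq))):
            i = 0
            while i + k <= len(seq):
                hits = index.get(seq[i: i + k])
                if not hits:
                    i += 1
                    continue
                best_end = i
                for sid, pos in hits:
                    gseq = genome[sid]
                    lo_q, lo_g = i, pos
                    while lo_q > 0 and lo_g > 0 and seq[lo_q - 1] == gseq[lo_g - 1] != "N":
                        lo_q -= 1
                        lo_g -= 1
                    hi_q, hi_g = i + k, pos + k
                    while (hi_q < len(seq) and hi_g < len(gseq)
                           and seq[hi_q] == gseq[hi_g] != "N"):
                        hi_q += 1
                        hi_g += 1
                    if hi_q - lo_q < min_seg:
                        continue
                    if strand == "+":
                        q_lo, q_hi = lo_q, hi_q
                    else:
                        q_lo, q_hi = tlen - hi_q, tlen - lo_q
                    key = (q_lo, q_hi, sid, lo_g, hi_g, strand)
                    if key not in seen:
                        seen.add(key)
                        segments.append(AlignmentSegment(
                            transcript_id=tid, q_start=q_lo, q_end=q_hi,
                            scaffold_id=sid, g_start=lo_g, g_end=hi_g,
                            strand=strand, matches=hi_q - lo_q,
                        ))
                    best_end = max(best_end, hi_q)
                i = max(best_end - k + 1, i + 1)
    return segments
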