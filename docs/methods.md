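# Methods

This document describes the computational model each stage implements, the
default parameters and why they hold those values, what the synthetic
fixture generator does and does not emulate, and the numerical conventions
used throughout.

## 1. Read quality control (`readqc`)

A read fails QC when any of five rules fires:

1. an `N` occurs within the first 30 nt (1-based positions 1–30 inclusive);
2. more than 3 bases have quality < 10;
3. more than 4 bases have quality < 13;
4. more than 60% of bases have quality < 20;
5. the mean base quality is < 20.

All failing rules are reported, not just the first. Surviving reads are
trimmed to their 5'-most 50 nt (3' ends of 101-nt short reads concentrate
miscalls). Pairs route to three bins: both mates pass → kept pair; one
passes → orphan single; neither → discarded. Read count is conserved:
`2·kept + orphans + discarded = total`.

## 2. Alignment interpretation (`psl`, `txalign`)

**PSL conventions.** 21-column PSL; for `-` strand records the stored
`qStarts` are in reversed-query coordinates and are converted to
forward-query coordinates on read (`q_forward = q_size − q_native − block`).
Target coordinates are always forward.

**Segments.** A record's blocks are split into *segments* at query-coordinate
gaps. Blocks contiguous in the query but jumping in the target (introns)
merge into one segment: only unaligned *transcript* sequence is structural
evidence.

**Optimal chain.** Per transcript, the chain maximising total matched bases
over segments pairwise non-overlapping in transcript coordinates — weighted
interval scheduling solved exactly by dynamic programming (sort by `q_end`,
binary-search predecessor). Ties break toward fewer segments, then earlier
genomic coordinates, for determinism. Tested against exhaustive subset
search.

**Connection classes** for multi-scaffold chains:

- `OK_merge` — a host/insert/host sandwich: the middle scaffold's aligned
  span fits inside an N-run of the flanking scaffold whose predicted length
  is at least that span. Checked before joins.
- `OK_join` — every cross-scaffold transition links a scaffold end to a
  scaffold start (within `edge_tol`, default 50 bp) with equal strands.
- `PB_merge` — everything else; reported, never edited (likely
  mis-assembly).

**Within-scaffold detectors**, applied only to single-scaffold chains so a
merge sandwich is never double-reported as a gap closure:

- *strand inconsistency*: consecutive same-scaffold segments must be
  ascending in genome order with pattern `++` or descending with `--`;
  any other combination is called.
- *nest*: consecutive segments whose genome footprints overlap by
  ≥ `nest_min_overlap` (default 20 bp) indicate a collapsed repeat copy.
- *boundary extension*: an unaligned transcript end abutting a scaffold
  boundary (within `edge_tol`) supplies the extension sequence, oriented to
  the genome forward strand (reverse-complemented for `-` chains).
- *gap closure*: an internal unaligned span whose flanking segments bracket
  an N-run supplies fill sequence; the call records the filled length, the
  N-run's predicted length, and whether they match exactly.

## 3. Genome editing and statistics (`genomefix`)

The gap map records maximal N-runs of length ≥ 10 (runs below that are
treated as ambiguity codes, not assembly gaps). The editor applies gap
fills and boundary extensions under the `conservative` policy (default);
`with-joins` additionally concatenates `OK_join` pairs with a fixed 100-N
spacer (the true gap length at a join is unknown). Edits are validated
(fills must target an N-run), conflict-checked (overlapping fills, duplicate
same-side extensions, scaffold reuse across joins all raise), de-duplicated
when several transcripts support the identical edit, and logged AGP-style
with old/new coordinates. Sequence outside edited intervals is
byte-identical to the input.

Contig N50/N90: largest L such that contigs of length ≥ L contain ≥ 50%
(90%) of the summed contig length; contigs are scaffold stretches between
mapped gaps. Tested against a brute-force oracle.

## 4. Novel-gene screen (`novelscreen`)

Two candidate branches mirror the two assembly routes:

- **reference-free branch** — aligned transcripts (single scaffold, single
  strand) become candidates directly; unaligned transcripts are clustered
  at ≥ 95% identity (greedy, descending length, representative = longest;
  identity computed by infix alignment of the shorter sequence, an
  `edlib`-based stand-in for cd-hit-est) and representatives with a
  non-coding-RNA hit at e ≤ 1e-5 are removed.
- **reference-dependent branch** — transcripts assembled against the genome
  carry per-tissue FPKM; candidates with max-pooled FPKM < 1 are removed.

Classification against known gene models, in precedence order: `match`
(identical intron chain, or ≥ 90% reciprocal overlap for mono-exon
transcripts), `overlap_known` (same-strand exonic overlap, or within a
5 kb flank of a model), `repeat_rejected` (≥ 50% of exonic bases
repeat-masked), `intronic_novel` (wholly inside a model intron, no
opposite-strand exon overlap), `antisense_novel` (opposite-strand exonic
overlap only; trusted only for `+`-aligned candidates), `intergenic_novel`
otherwise. The two branches' novel sets merge by transitive same-strand
exon overlap, keeping the longest member of each component (longer
transcripts carry more coding information).

## 5. ORF and homology tiers (`orfhomology`)

A gene is *full-length* when its ORF has both a start and a stop codon and
a CDS strictly longer than 150 bp; missing codons ⇒ `rejected_partial`
(takes precedence), short CDS ⇒ `rejected_small`.

A homology hit qualifies when e-value ≤ 1e-5 and the aligned length is
≥ 10 aa (protein db `nr`) or ≥ 20 nt (nucleotide dbs `nt`, `dbEST`).
Per query/target pair, coverage is

```
coverage = 100 · (merged aligned target span − Σ gap_size) / target_length
```

with overlapping target intervals merged before summation (no double
counting; tested against a per-base bitmap) and the result capped to
[0, 100]. A database supports a query when some single target reaches
≥ 95% coverage.

Tiers for full-length ORFs: `nr` or `nt` support ⇒ **homology_based**;
`dbEST` only ⇒ **unknown**; none ⇒ **hypothetical**.

## 6. Proteomic validation (`protvalid`)

Peptide-spectrum matches pass when Sp ≥ 500, RSp ≤ 5 and XCorr reaches the
charge-dependent floor (1.5 / 2.0 / 2.5 / 3.0 for charges 1–4); other
charges are rejected with a warning. A gene is validated by ≥ 2 distinct
peptide sequences among its passing hits (pooled across tissues by default;
a per-tissue mode exists). Validation percentage = 100·validated/expressed,
rounded to two decimals; zero expressed genes is an error, as is
validated > expressed.

## 7. Descriptive statistics (`summary`)

GC content is computed over unambiguous bases only (all-N sequences are
excluded and counted); GC histograms use 5-point bins, CDS lengths 0.1-kb
bins, expression breadth = number of tissues at FPKM ≥ 1. Distribution
comparison is the two-sided Wilcoxon rank-sum test via
`scipy.stats.mannwhitneyu(method="asymptotic", use_continuity=False)` —
normal approximation with tie correction. The fully degenerate case (every
observation in both samples identical) would give zero rank variance and an
undefined p; it is special-cased to p = 1.0 (no evidence of a shift).

## 8. Fixture generator (`fixtures`)

The generator builds a "true" genome of 180 × 6 kb scaffolds (~1.08 Mb),
derives a damaged draft by planting typed defects — each on its own
scaffold so recovery is attributable — and emits every pipeline input plus
a JSON truth ledger:

- **join**: a true scaffold split in two; a spanning transcript aligns
  FLANK (300 bp) into each half, alternating `++` / `--` chains.
- **merge**: an interior block excised to its own scaffold and replaced by
  an N-run at least as long; a transcript crosses host–insert–host.
- **strand inconsistency**: an interior block reverse-complemented.
- **nest**: one copy of a true tandem duplication collapsed in the draft.
- **boundary extension**: a scaffold end truncated; the transcript covers
  all truncated bases, so the accepted edit restores the truth exactly.
- **gap fill**: an interior block replaced by an N-run whose length
  mis-estimates the truth with probability `gap_predicted_error`.

Alignments are generated analytically (block coordinates follow from the
construction, verified by a sequence-consistency test over every emitted
block) rather than by running an aligner. Evidence tables (homology hits,
peptides, FPKM) are synthesised directly from the planted labels with
values strictly clear of every decision threshold, so tier and validation
recovery are exact at any seed. Counts that tests pin (events per kind,
tier quotas, full-length quota) are deterministic; which gene receives
which label, all sequence content, and Bernoulli-rate quantities
(validated genes, exactly-sized gaps) vary with the seed.

Default rates — `gap_predicted_error = 0.9336` (≈ 6.6% of gaps exactly
sized), `tier_mix = (0.0284, 0.3240, 0.6476)`, `full_length_fraction =
0.6805`, `peptide_hit_rate = 0.1262` — are chosen so the synthetic
pipeline's summary statistics fall in realistic ranges for a
transcript-guided assembly-improvement study; they are configuration, not
assertions, and every test scores against the per-run truth ledger.

**What the generator does not emulate:** sequencing error and alignment
noise (alignments are exact by construction), paralogy/multi-mapping,
chimeric transcripts, incomplete transcript assemblies, realistic repeat
families (repeats are coordinate intervals only), homology-score
distributions (values are planted clear of thresholds), and spectral search
(peptide rows are synthesised, not searched). Consequently
precision = recall = 1.0 on fixtures is a correctness statement about the
decision logic, not a performance claim about noisy data.

`fixtures.align_exact` (exact k-mer seed-and-extend, k = 24) re-aligns
transcripts to the *edited* genome for the idempotence check — applied
edits restore true sequence exactly, so an exact aligner suffices and no
external alignment tool is needed.

## 9. Numerical conventions

- Percentages reported to two decimals (`round`, banker's at half-ulp as in
  Python); counts are exact integers.
- All interval coordinates in memory are 0-based half-open; GTF is
  converted at the file boundary (1-based closed on disk), PSL `-` strand
  at parse time.
- Arithmetic cross-checks recomputed from printed study counts: a
  validation table row of 56/342 gives 16.37%, the three tier counts
  551 + 6,290 + 12,575 sum to 19,416 and yield 1.93% / 22.05% / 44.09% of
  28,522 candidates (the middle figure is misprinted as 22.03% at source),
  and the three connection components 741 + 79 + 1,503 sum to 2,323 against
  a printed table total of 2,317 — an unexplained 6-count discrepancy, so
  recovery tests score against fixture truth, never against those counts.

## 10. Limitations

- The connection classifier assumes each transcript's optimal chain is the
  correct placement; paralogous placements with equal scores resolve by a
  deterministic tie-break, not by biological evidence.
- `OK_merge` detection requires the host/insert/host sandwich within one
  chain; merges supported only by two separate transcripts are not called.
- Join edits use a fixed 100-N spacer because the true inter-scaffold gap
  length is unobservable from transcript evidence.
- The ncRNA filter and the homology thresholds treat the hit tables as
  given; no search heuristics or e-value calibration are modelled.
- Validation percentages treat the peptide-to-gene assignment as given;
  protein inference over shared peptides is out of scope.
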