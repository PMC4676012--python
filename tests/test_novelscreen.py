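"""Clustering, ncRNA removal, locus building, model classification and merging."""

import random

import pytest

from txrefine.gtfio import GtfTranscript
from txrefine.novelscreen import (
    CandidateTranscript,
    ModelIndex,
    build_loci,
    classify_vs_models,
    fpkm_filter,
    greedy_identity_cluster,
    merge_candidate_sets,
    remove_ncrna_hits,
)


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def cand(tid, exons, scaffold="s1", strand="+", fpkm=None, source="denovo_aligned"):
    return CandidateTranscript(
        id=tid, source=source, scaffold=scaffold, strand=strand,
        exons=list(exons), fpkm=fpkm or {},
    )


def model(tid, exons, scaffold="s1", strand="+"):
    return GtfTranscript(tid, tid, scaffold, strand, sorted(exons))


# -- clustering ----------------------------------------------------------------

def test_identical_sequences_one_cluster():
    rng = random.Random(1)
    s = rand_seq(rng, 500)
    clusters, dropped = greedy_identity_cluster({"b": s, "a": s})
    assert dropped == 0
    assert len(clusters) == 1
    assert clusters[0].representative == "a"  # length tie -> smallest id
    assert sorted(clusters[0].members) == ["a", "b"]


def test_substring_joins_longest_representative():
    rng = random.Random(2)
    long = rand_seq(rng, 600)
    clusters, _ = greedy_identity_cluster({"short": long[10:590], "long": long})
    assert len(clusters) == 1 and clusters[0].representative == "long"


def test_ninety_percent_identity_stays_apart():
    rng = random.Random(3)
    s = rand_seq(rng, 500)
    # mutate 10% of positions -> below the 0.95 identity bar
    mutated = list(s)
    for i in rng.sample(range(500), 50):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    clusters, _ = greedy_identity_cluster({"a": s, "b": "".join(mutated)})
    assert len(clusters) == 2


def test_min_length_dropped():
    clusters, dropped = greedy_identity_cluster({"tiny": "ACGT" * 10})
    assert clusters == [] and dropped == 1


# -- ncRNA removal ----------------------------------------------------------------

def test_ncrna_removal_arithmetic():
    reps = {f"r{i}" for i in range(40)}
    hits = [{"transcript_id": "r0", "target_id": "x", "evalue": 1e-8},
            {"transcript_id": "r1", "target_id": "y", "evalue": 1e-9}]
    kept, removed = remove_ncrna_hits(reps, hits)
    assert len(kept) == 38 and removed == {"r0", "r1"}


def test_ncrna_no_hits_identity():
    kept, removed = remove_ncrna_hits({"a", "b"}, [])
    assert kept == {"a", "b"} and removed == set()


def test_ncrna_weak_hit_ignored():
    kept, removed = remove_ncrna_hits(
        {"a"}, [{"transcript_id": "a", "target_id": "x", "evalue": 1e-3}]
    )
    assert kept == {"a"} and removed == set()


def test_ncrna_all_hit_empty():
    kept, _ = remove_ncrna_hits(
        {"a"}, [{"transcript_id": "a", "target_id": "x", "evalue": 1e-9}]
    )
    assert kept == set()


# -- loci ---------------------------------------------------------------------------

def test_shared_exon_one_locus():
    loci = build_loci([cand("a", [(100, 300)]), cand("b", [(200, 500)])])
    assert len(loci) == 1
    assert loci[0].representative == "b"  # longer member
    assert loci[0].span == ("s1", 100, 500)


def test_opposite_strands_two_loci():
    loci = build_loci(
        [cand("a", [(100, 300)]), cand("b", [(100, 300)], strand="-")]
    )
    assert len(loci) == 2


def test_loci_match_component_oracle():
    rng = random.Random(9)
    ts = []
    for i in range(50):
        s = rng.randrange(0, 5000)
        ts.append(cand(f"t{i:02d}", [(s, s + rng.randint(50, 400))],
                       strand=rng.choice("+-")))
    loci = build_loci(ts)
    # oracle: transitive closure of pairwise same-strand span overlap
    parent = {t.id: t.id for t in ts}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a in ts:
        for b in ts:
            if a.strand == b.strand and a.span[0] < b.span[1] and b.span[0] < a.span[1]:
                ra, rb = find(a.id), find(b.id)
                parent[ra] = rb
    oracle = {}
    for t in ts:
        oracle.setdefault(find(t.id), set()).add(t.id)
    assert sorted(sorted(m) for m in oracle.values()) == sorted(
        l.members for l in loci
    )


# -- classification ---------------------------------------------------------------

MODELS = [
    model("m1", [(1000, 1200), (1800, 2000)]),           # spliced '+' model
    model("m2", [(8000, 8600)], strand="+"),             # mono-exon model
]


def make_index():
    return ModelIndex(MODELS, flank=500)


def test_identical_intron_chain_matches():
    t = cand("t", [(950, 1200), (1800, 2100)])
    assert classify_vs_models(t, make_index()) == "match"


def test_mono_exon_reciprocal_overlap_matches():
    t = cand("t", [(8010, 8590)])
    assert classify_vs_models(t, make_index()) == "match"


def test_same_strand_exon_overlap_known():
    t = cand("t", [(1100, 1500)])  # overlaps m1 exon, different structure
    assert classify_vs_models(t, make_index()) == "overlap_known"


def test_intronic_same_strand_novel():
    t = cand("t", [(1300, 1700)])  # wholly inside m1's intron
    assert classify_vs_models(t, make_index()) == "intronic_novel"


def test_antisense_novel():
    t = cand("t", [(1050, 1150)], strand="-")
    assert classify_vs_models(t, make_index()) == "antisense_novel"


def test_repeat_rejected_at_half():
    t = cand("t", [(4000, 4400)])
    repeats = {"s1": [(4000, 4240)]}  # 60% masked
    assert classify_vs_models(t, make_index(), repeats) == "repeat_rejected"
    light = {"s1": [(4000, 4100)]}  # 25% masked
    assert classify_vs_models(t, make_index(), light) == "intergenic_novel"


def test_flank_proximity_demoted_to_overlap_known():
    t = cand("t", [(2100, 2400)])  # within 500 bp of m1, no exon overlap
    assert classify_vs_models(t, make_index()) == "overlap_known"


def test_scaffold_without_models_is_intergenic():
    t = cand("t", [(100, 400)], scaffold="lonely")
    assert classify_vs_models(t, make_index()) == "intergenic_novel"


# -- abundance filter -----------------------------------------------------------------

def test_fpkm_below_one_everywhere_removed():
    t = cand("t", [(0, 100)], fpkm={"a": 0.99, "b": 0.5})
    kept, removed = fpkm_filter([t])
    assert kept == [] and removed == [t] and t.tag == "low_abundance_rejected"


def test_fpkm_exactly_one_kept():
    t = cand("t", [(0, 100)], fpkm={"a": 1.0})
    kept, _ = fpkm_filter([t])
    assert kept == [t]


def test_fpkm_max_pooled():
    t = cand("t", [(0, 100)], fpkm={"a": 0.2, "b": 3.5})
    kept, _ = fpkm_filter([t])
    assert kept == [t]


# -- set merging ---------------------------------------------------------------------

def test_disjoint_sets_union():
    a = [cand("a", [(0, 100)])]
    b = [cand("b", [(1000, 1100)])]
    assert {t.id for t in merge_candidate_sets(a, b)} == {"a", "b"}


def test_overlapping_pair_keeps_longest():
    a = [cand("a", [(0, 700)])]
    b = [cand("b", [(100, 600)])]
    assert [t.id for t in merge_candidate_sets(a, b)] == ["a"]


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        merge_candidate_sets([cand("a", [(0, 100)])], [cand("a", [(0, 100)])])


def test_merge_matches_component_oracle():
    rng = random.Random(17)
    a, b = [], []
    for i in range(10):
        base = i * 2000
        # each group: one long A transcript and one or two shorter B twins
        a.append(cand(f"a{i}", [(base, base + 900)]))
        b.append(cand(f"b{i}", [(base + 100, base + 800)], source="reference_based"))
        if i % 2:
            b.append(cand(f"c{i}", [(base + 200, base + 700)], source="reference_based"))
    merged = merge_candidate_sets(a, b)
    assert sorted(t.id for t in merged) == [f"a{i}" for i in range(10)]


def test_fixture_classification_controls(fx, screen):
    for tid, want in fx.truth.aux["classification_controls"].items():
        assert screen.tags[tid] == want, tid
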