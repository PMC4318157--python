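"""Haplotype assignment, DAE calling, LOH run detection, in-silico digest."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermase import allelic
from fermase.align import FeatureIndex
from fermase.allelic import (
    AlleleCountRecord,
    DaeCall,
    GeneModel,
    accumulate_gene_alleles,
    assign_read_haplotype,
    call_dae,
    compare_conditions,
    dae_boundary_percent,
    detect_loh_runs,
    exclude_region,
    insilico_digest,
)
from tests.conftest import brute_force_loh


def _gene(snps, start=101, end=400, gid="gX", chrom="chr01"):
    return GeneModel(gene_id=gid, chrom=chrom, start=start, end=end, snps=snps)


# ---------------------------------------------------------------------------
# per-read assignment and accumulation


def test_read_votes_follow_covered_snp_bases():
    g = _gene([(121, "A", "G"), (181, "C", "T")])
    # gene-relative SNP offsets 20 and 80
    seq = ["T"] * 120
    seq[20] = "A"
    seq[80] = "C"
    h1 = "".join(seq)
    assert assign_read_haplotype(h1[10:46], 10, g) == "h1"  # covers SNP1 only
    h2 = h1[:20] + "G" + h1[21:80] + "T" + h1[81:]
    assert assign_read_haplotype(h2[60:96], 60, g) == "h2"  # covers SNP2 only
    long_mixed = h1[:80] + "T" + h1[81:]  # SNP1 h1-base, SNP2 h2-base
    assert assign_read_haplotype(long_mixed[15:95], 15, g) == "conflicting"
    assert assign_read_haplotype(h1[30:66], 30, g) == "uninformative"
    neither = h1[:20] + "T" + h1[21:]  # third allele at SNP1
    assert assign_read_haplotype(neither[10:46], 10, g) == "conflicting"


def _haplotype_pair(seed=3, length=300):
    """Random gene haplotypes differing at offsets 20 (A/G) and 80 (C/T)."""
    rng = np.random.default_rng(seed)
    s = ["ACGT"[i] for i in rng.integers(0, 4, length)]
    s[20], s[80] = "A", "C"
    h1 = "".join(s)
    h2 = h1[:20] + "G" + h1[21:80] + "T" + h1[81:]
    return h1, h2


def test_read_spanning_two_snps_counts_once():
    g = _gene([(121, "A", "G"), (141, "C", "T")], end=300)
    rng = np.random.default_rng(8)
    s = ["ACGT"[i] for i in rng.integers(0, 4, 200)]
    s[20], s[40] = "A", "C"
    h1 = "".join(s)
    index = FeatureIndex(["gX"], [h1])
    reads = [("r1", h1[10:60])]  # covers both SNPs, unanimous h1
    aln = index.align(reads)
    rec = accumulate_gene_alleles(aln, reads, {"gX": g}, "TF")["gX"]
    assert (rec.reads_h1, rec.reads_h2, rec.reads_conflicting) == (1, 0, 0)


def test_accumulation_hand_tally():
    g = _gene([(121, "A", "G"), (181, "C", "T")], end=400)
    h1, h2 = _haplotype_pair()
    index = FeatureIndex(["gX"], [h1])
    reads = (
        [(f"a{i}", h1[5:41]) for i in range(10)]  # 10 h1 reads at SNP1
        + [(f"b{i}", h1[70:106]) for i in range(20)]  # 20 h1 reads at SNP2
        + [(f"c{i}", h2[70:106]) for i in range(15)]  # 15 h2 reads at SNP2
    )
    aln = index.align(reads)
    rec = accumulate_gene_alleles(aln, reads, {"gX": g}, "TF")["gX"]
    assert (rec.reads_h1, rec.reads_h2, rec.reads_conflicting) == (30, 15, 0)
    assert rec.informative_depth == 45


def test_no_informative_reads_gives_zero_record():
    g = _gene([(121, "A", "G")])
    index = FeatureIndex(["gX"], ["ACGT" * 100])
    aln = index.align([])
    rec = accumulate_gene_alleles(aln, [], {"gX": g}, "TF")["gX"]
    assert (rec.reads_h1, rec.reads_h2, rec.reads_conflicting) == (0, 0, 0)


# ---------------------------------------------------------------------------
# DAE calls


@pytest.mark.parametrize(
    "h1,h2,expected",
    [
        (67, 33, "allele1"),  # ratio 2.03, fraction 67%
        (33, 67, "allele2"),
        (50, 50, "balanced"),
        (66, 34, "balanced"),  # ratio 1.94 < 2
        (100, 50, "allele1"),  # exactly 2:1 qualifies
        (10, 0, "uninformative"),  # below min_depth 20
        (0, 0, "uninformative"),
    ],
)
def test_two_fold_rule_with_boundary(h1, h2, expected):
    call = call_dae(AlleleCountRecord("g", "TF", h1, h2))
    assert call.call == expected


def test_boundary_percentage_rounds_down_to_66():
    assert dae_boundary_percent() == 66
    assert math.floor(100 * 2 / 3) == 66


def test_ratio_and_fraction_fields():
    c = call_dae(AlleleCountRecord("g", "TF", 60, 20))
    assert c.allele1_fraction == pytest.approx(0.75)
    assert c.allelic_ratio == pytest.approx(3.0)
    assert call_dae(AlleleCountRecord("g", "TF", 40, 0)).allelic_ratio == math.inf


@given(
    h1=st.integers(0, 500),
    h2=st.integers(0, 500),
    min_depth=st.integers(1, 50),
)
@settings(max_examples=200, deadline=None)
def test_allele_swap_symmetry(h1, h2, min_depth):
    a = call_dae(AlleleCountRecord("g", "TF", h1, h2), min_depth)
    b = call_dae(AlleleCountRecord("g", "TF", h2, h1), min_depth)
    swap = {"allele1": "allele2", "allele2": "allele1"}
    assert b.call == swap.get(a.call, a.call)
    if a.call != "uninformative":
        assert a.allele1_fraction + b.allele1_fraction == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# LOH runs


def _calls_and_genes(statuses):
    """Build DaeCall/GeneModel lists realising a status string (1/2/u/h)."""
    calls, genes = [], []
    pos = 1
    for i, s in enumerate(statuses):
        if s == "1":
            h1, h2 = 100, 0
        elif s == "2":
            h1, h2 = 0, 100
        elif s == "h":
            h1, h2 = 50, 50
        else:
            h1, h2 = 0, 0
        calls.append(call_dae(AlleleCountRecord(f"g{i}", "TF", h1, h2)))
        genes.append(GeneModel(f"g{i}", "chrT", pos, pos + 999))
        pos += 2000
    return calls, genes


def test_alternating_haplotypes_yield_no_segment():
    calls, genes = _calls_and_genes("12" * 10)
    assert detect_loh_runs(calls, genes, min_genes=2) == []


def test_140_consecutive_monoallelic_genes_form_one_segment():
    calls, genes = _calls_and_genes("h" * 5 + "1" * 140 + "h" * 5)
    segs = detect_loh_runs(calls, genes)
    assert len(segs) == 1
    assert segs[0].gene_count == 140
    assert segs[0].dominant_haplotype == 1
    assert segs[0].first_gene == "g5" and segs[0].last_gene == "g144"


def test_single_uninformative_gap_is_bridged():
    calls, genes = _calls_and_genes("1" * 10 + "u" + "1" * 10)
    segs = detect_loh_runs(calls, genes)
    assert len(segs) == 1
    assert segs[0].gene_count == 20  # informative genes only
    # span covers the gap: first gene start .. last gene end
    assert segs[0].span_bp == genes[20].end - genes[0].start + 1


def test_gap_longer_than_allowance_splits_the_run():
    calls, genes = _calls_and_genes("1" * 10 + "uuu" + "1" * 10)
    segs = detect_loh_runs(calls, genes, max_uninformative_gap=2)
    assert [s.gene_count for s in segs] == [10, 10]


def test_short_runs_are_discarded_and_refiltering_is_idempotent():
    calls, genes = _calls_and_genes("1" * 9 + "h" + "1" * 12)
    segs = detect_loh_runs(calls, genes, min_genes=10)
    assert [s.gene_count for s in segs] == [12]
    all_segs = detect_loh_runs(calls, genes, min_genes=1)
    refiltered = [s for s in all_segs if s.gene_count >= 10]
    assert [(s.first_index, s.last_index) for s in refiltered] == [
        (s.first_index, s.last_index) for s in segs
    ]


def test_unsorted_genes_rejected():
    calls, genes = _calls_and_genes("111")
    with pytest.raises(ValueError, match="sorted"):
        detect_loh_runs(list(reversed(calls)), list(reversed(genes)))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
def test_detector_matches_exhaustive_window_enumeration(seed):
    rng = np.random.default_rng(seed)
    statuses = "".join(rng.choice(list("12uh"), p=[0.35, 0.15, 0.2, 0.3], size=40))
    calls, genes = _calls_and_genes(statuses)
    got = detect_loh_runs(calls, genes, min_genes=3, max_uninformative_gap=2)
    expected = brute_force_loh(statuses, min_genes=3, max_gap=2)
    assert [
        (s.first_index, s.last_index, s.gene_count, s.dominant_haplotype)
        for s in got
    ] == expected
    # segments are disjoint
    for a, b in zip(got, got[1:]):
        assert a.last_index < b.first_index


# ---------------------------------------------------------------------------
# region exclusion and condition comparison


def test_exclude_region_boundaries():
    calls, genes = _calls_and_genes("1111")
    cd = {c.gene_id: c for c in calls}
    gd = {g.gene_id: g for g in genes}
    assert exclude_region(cd, gd, "chrT", 10**9) == cd  # beyond the end
    assert exclude_region(cd, gd, "chrT", 1) == {}  # everything removed
    kept = exclude_region(cd, gd, "chrT", genes[2].start)
    assert set(kept) == {"g0", "g1"}
    assert exclude_region(cd, gd, "chrOther", 1) == cd


def test_compare_conditions_set_algebra():
    def calls_for(dae_ids, universe):
        return {
            gid: DaeCall(gid, "c", 90, 10, 0.9, 9.0, "allele1")
            if gid in dae_ids
            else DaeCall(gid, "c", 50, 50, 0.5, 1.0, "balanced")
            for gid in universe
        }

    universe = [f"g{i}" for i in range(10)]
    a = calls_for({"g1", "g2", "g3"}, universe)
    same = compare_conditions(a, a)
    assert same["both"] == {"g1", "g2", "g3"}
    assert same["A_only"] == set() and same["B_only"] == set()
    b = calls_for({"g4", "g5"}, universe)
    disjoint = compare_conditions(a, b)
    assert disjoint["both"] == set()
    assert disjoint["A_only"] == {"g1", "g2", "g3"}
    assert disjoint["B_only"] == {"g4", "g5"}
    with pytest.raises(ValueError, match="universe"):
        compare_conditions(a, calls_for(set(), universe[:5]))


# ---------------------------------------------------------------------------
# restriction digest


def test_digest_no_site_returns_whole_length():
    assert insilico_digest("A" * 500) == [500]


def test_digest_reproduces_marker_fragments():
    """One GATC site at position 544 of a 799-bp amplicon: 543 + 256 bp."""
    seq = ["A"] * 799
    seq[543:547] = list("GATC")
    frags = insilico_digest("".join(seq))
    assert frags == [543, 256]
    # the SNP-destroyed (uncut) allele leaves one 799-bp fragment
    uncut = "".join(seq[:543] + ["A"] + seq[544:])
    assert insilico_digest(uncut) == [799]


@given(st.text(alphabet="ACGT", min_size=1, max_size=300))
@settings(max_examples=100, deadline=None)
def test_digest_fragments_conserve_length(seq):
    frags = insilico_digest(seq)
    assert sum(frags) == len(seq)
    assert all(f > 0 for f in frags)


def test_digest_rejects_empty_sequence():
    with pytest.raises(ValueError):
        insilico_digest("")


def test_gene_model_validation():
    with pytest.raises(ValueError, match="outside"):
        GeneModel("g", "c", 100, 200, snps=[(300, "A", "C")])
    with pytest.raises(ValueError, match="increasing"):
        GeneModel("g", "c", 100, 200, snps=[(150, "A", "C"), (150, "G", "T")])
    with pytest.raises(ValueError, match="identical"):
        GeneModel("g", "c", 100, 200, snps=[(150, "A", "A")])
    with pytest.raises(ValueError, match="start"):
        GeneModel("g", "c", 200, 100)
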