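"""rRNA read classification, rank aggregation, family cutoff, LCA ties."""

import numpy as np
import pandas as pd
import pytest

from fermase import taxonomy
from fermase.taxonomy import (
    apply_family_cutoff,
    build_rrna_index,
    classify_reads,
    counts_per_taxon,
    dominant_species_fraction,
    lca,
    lineage_at,
    parse_lineage,
    species_fraction,
)

LIN_A = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus fermentum"
LIN_B = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus vini"
LIN_C = "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;Acetobacteraceae;Acetobacter;Acetobacter pasteurianus"


def _rand_seq(rng, n=150):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_parse_lineage_and_rank_access():
    lin = parse_lineage(LIN_A)
    assert len(lin) == 7
    assert lineage_at(lin, "family") == "Lactobacillaceae"
    assert lineage_at(lin, "species") == "Lactobacillus fermentum"
    partial = parse_lineage("Bacteria;Firmicutes")
    assert lineage_at(partial, "family") is None


def test_lca_truncates_at_first_disagreement():
    a, b, c = parse_lineage(LIN_A), parse_lineage(LIN_B), parse_lineage(LIN_C)
    assert lca([a, b]) == a[:6]  # shared through genus
    assert lca([a, c]) == ("Bacteria",)
    assert lca([a]) == a
    assert lca([]) == ()


def test_exact_match_adopts_full_lineage_and_far_reads_unassigned():
    rng = np.random.default_rng(0)
    refs = [("rA", LIN_A, _rand_seq(rng)), ("rC", LIN_C, _rand_seq(rng))]
    index = build_rrna_index(refs)
    read_a = refs[0][2][40:76]
    junk = _rand_seq(rng, 36)  # unrelated: >2 mismatches from both refs
    out = classify_reads([("x", read_a), ("y", junk)], index)
    assert out[0] == parse_lineage(LIN_A)
    assert out[1] == ()


def test_species_level_tie_salvaged_at_genus_by_lca():
    rng = np.random.default_rng(1)
    shared = _rand_seq(rng)
    refs = [("r1", LIN_A, shared), ("r2", LIN_B, shared)]
    index = build_rrna_index(refs)
    read = shared[10:46]
    assert classify_reads([("x", read)], index)[0] == parse_lineage(LIN_A)[:6]
    # strict mode reproduces plain repeat discarding
    assert classify_reads([("x", read)], index, strict=True)[0] == ()


def test_tie_with_no_shared_ancestry_below_domain_is_kept_at_domain():
    rng = np.random.default_rng(2)
    shared = _rand_seq(rng)
    refs = [("r1", LIN_A, shared), ("r2", LIN_C, shared)]
    index = build_rrna_index(refs)
    assert classify_reads([("x", shared[0:36])], index)[0] == ("Bacteria",)


def test_counts_per_taxon_tallies_and_unresolved_bucket():
    assert counts_per_taxon([], "family").empty
    lineages = [parse_lineage(LIN_A)] * 7 + [parse_lineage(LIN_C)] * 3
    fam = counts_per_taxon(lineages, "family")
    assert fam.set_index("taxon")["count"].to_dict() == {
        "Lactobacillaceae": 7,
        "Acetobacteraceae": 3,
    }
    assert fam.set_index("taxon")["fraction"].to_dict() == pytest.approx(
        {"Lactobacillaceae": 0.7, "Acetobacteraceae": 0.3}
    )
    mixed = lineages + [parse_lineage("Bacteria;Firmicutes")] + [()]
    fam2 = counts_per_taxon(mixed, "family")
    unres = fam2[fam2["taxon"] == "unresolved"]
    assert unres["count"].iloc[0] == 2
    with pytest.raises(ValueError):
        counts_per_taxon(lineages, "kingdom")


def test_family_counts_bound_genus_counts():
    rng = np.random.default_rng(3)
    pool = [parse_lineage(LIN_A), parse_lineage(LIN_B), parse_lineage(LIN_C),
            parse_lineage("Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae")]
    lineages = [pool[i] for i in rng.integers(0, len(pool), 200)]
    fam = counts_per_taxon(lineages, "family").set_index("taxon")["count"]
    gen = counts_per_taxon(lineages, "genus").set_index("taxon")["count"]
    assert fam["Lactobacillaceae"] >= gen.get("Lactobacillus", 0)
    # conservation at every rank: resolved + unresolved = total reads
    for rank in taxonomy.RANKS:
        t = counts_per_taxon(lineages, rank)
        assert t["count"].sum() == len(lineages)


def test_family_cutoff_boundary():
    fam = pd.DataFrame(
        {
            "taxon": ["A", "B", "C"],
            "rank": ["family"] * 3,
            "count": [910, 50, 40],
            "fraction": [0.91, 0.05, 0.04],
        }
    )
    kept = apply_family_cutoff(fam, 0.05)
    assert kept["taxon"].tolist() == ["A", "B"]  # exactly 5% retained, 4% dropped
    solo = apply_family_cutoff(fam.iloc[:1].assign(fraction=1.0), 0.05)
    assert solo["taxon"].tolist() == ["A"]


def test_species_fraction_and_errors():
    lineages = [parse_lineage(LIN_A)] * 93 + [parse_lineage(LIN_B)] * 7
    assert species_fraction(
        lineages, "Lactobacillaceae", "Lactobacillus fermentum"
    ) == pytest.approx(0.93)
    assert species_fraction(
        [parse_lineage(LIN_A)], "Lactobacillaceae", "Lactobacillus fermentum"
    ) == 1.0
    sp, frac = dominant_species_fraction(lineages, "Lactobacillaceae")
    assert sp == "Lactobacillus fermentum" and frac == pytest.approx(0.93)
    with pytest.raises(ValueError, match="no reads"):
        species_fraction(lineages, "Bacillaceae", "Bacillus subtilis")


def test_simulated_mix_recovers_planted_fractions_exactly():
    """Error-free reads + unique references: recovered rank fractions are exact."""
    from fermase import pipeline, sim

    cfg = sim.SimConfig(
        n_chromosomes=1,
        genes_per_chromosome=10,
        gene_length_range=(500, 900),
        snps_per_gene_range=(0, 1),
        intergenic_gap_range=(501, 900),
        reads_per_library=2000,
        informative_depth=10,
        rrna_mix={LIN_A: 0.30, LIN_B: 0.10, LIN_C: 0.20},
        seed=11,
    )
    res = pipeline.run_taxonomy_workflow(cfg)
    fam = res["family_counts"].set_index("taxon")
    assert fam.loc["Lactobacillaceae", "count"] == 800
    assert fam.loc["Acetobacteraceae", "count"] == 400
    assert fam.loc["Lactobacillaceae", "fraction"] == pytest.approx(800 / 1200)
    assert species_fraction(
        res["lineages"], "Lactobacillaceae", "Lactobacillus fermentum"
    ) == pytest.approx(0.75)
    # conservation: classified + unassigned = candidate reads
    n_classified = sum(1 for lin in res["lineages"] if lin)
    n_unassigned = sum(1 for lin in res["lineages"] if not lin)
    assert n_classified + n_unassigned == res["n_candidate_reads"]
    assert n_classified == 1200
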