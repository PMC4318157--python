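"""Taxonomic profiling of residual rRNA reads.

Libraries prepared with poly-A selection still carry a small fraction of
rRNA molecules; reads that fail to align to the gene/intergenic reference
can therefore be classified against a lineage-labelled rRNA reference
(SILVA-style FASTA, header taxonomy separated by semicolons) to profile the
bacterial community co-sampled with the yeast.

Classification uses the same <=2-mismatch matcher as gene alignment.  A
unique best hit adopts the reference's full lineage.  Reads whose best score
ties across references are salvaged by truncating to the lowest common
ancestor (LCA) of the tied lineages — a documented, information-preserving
variant of plain repeat discarding; ``strict=True`` reproduces the pure
discarding behaviour.  Family-level profiles drop families below a 5% share
of classified bacterial reads (the boundary is retained), and within-family
species fractions are reported for the survivors.
"""

from __future__ import annotations

import pandas as pd

from fermase.align import STATUS_ALIGNED, STATUS_REPEAT, FeatureIndex

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def parse_lineage(text: str) -> tuple:
    """Semicolon-delimited lineage string -> tuple of up to 7 rank names."""
    parts = [p.strip() for p in str(text).split(";") if p.strip()]
    if len(parts) > len(RANKS):
        parts = parts[: len(RANKS)]
    return tuple(parts)


def lineage_at(lineage: tuple, rank: str):
    """The taxon name of ``lineage`` at ``rank``, or None if unresolved."""
    i = RANKS.index(rank)
    return lineage[i] if len(lineage) > i else None


def lca(lineages) -> tuple:
    """Longest common prefix of several lineages (empty when none shared)."""
    lineages = list(lineages)
    if not lineages:
        return ()
    out = []
    for level in zip(*lineages):
        if all(t == level[0] for t in level):
            out.append(level[0])
        else:
            break
    return tuple(out)


def build_rrna_index(records, k: int = 12) -> FeatureIndex:
    """Index ``(ref_id, lineage_string, seq)`` records for classification."""
    records = list(records)
    idx = FeatureIndex([r[0] for r in records], [r[2] for r in records], k=k)
    idx.lineages = [parse_lineage(r[1]) for r in records]  # type: ignore[attr-defined]
    return idx


def classify_reads(
    reads,
    index: FeatureIndex,
    max_mismatches: int = 2,
    strict: bool = False,
) -> list:
    """Classify reads against the rRNA reference; one lineage tuple per read.

    Unassigned reads (no placement within the mismatch allowance, or
    unsalvageable ties) yield the empty lineage ``()``.
    """
    lineages = index.lineages  # set by build_rrna_index
    aln = index.align(reads, max_mismatches=max_mismatches, keep_ties=True)
    out = []
    for i in range(len(aln)):
        s = aln.status[i]
        if s == STATUS_ALIGNED:
            out.append(lineages[int(aln.feature[i])])
        elif s == STATUS_REPEAT and not strict:
            tied = [lineages[f] for f in aln.tie_features.get(i, [])]
            anc = lca(tied)
            # ties sharing nothing below the root are discarded outright
            out.append(anc if len(anc) >= 1 else ())
        else:
            out.append(())
    return out


def counts_per_taxon(lineages, rank: str) -> pd.DataFrame:
    """Exact read tallies at one rank, with an ``unresolved`` bucket.

    Fractions are over reads classified at this rank (the unresolved bucket
    is excluded from the denominator but reported).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    tallies: dict[str, int] = {}
    unresolved = 0
    for lin in lineages:
        name = lineage_at(lin, rank) if lin else None
        if name is None:
            unresolved += 1
        else:
            tallies[name] = tallies.get(name, 0) + 1
    total = sum(tallies.values())
    rows = [
        {
            "taxon": name,
            "rank": rank,
            "count": cnt,
            "fraction": cnt / total if total else 0.0,
        }
        for name, cnt in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if unresolved:
        rows.append(
            {"taxon": "unresolved", "rank": rank, "count": unresolved,
             "fraction": float("nan")}
        )
    return pd.DataFrame(rows, columns=["taxon", "rank", "count", "fraction"])


def apply_family_cutoff(
    family_counts: pd.DataFrame, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Drop families below ``min_fraction`` of classified reads (5% rule).

    A family at exactly the cutoff is retained.  The unresolved bucket is
    never subject to the cutoff.
    """
    keep = family_counts["taxon"] == "unresolved"
    keep |= family_counts["fraction"] >= min_fraction
    return family_counts[keep].reset_index(drop=True)


def species_fraction(lineages, family: str, species: str) -> float:
    """Share of a family's classified reads assigned to one species."""
    fam_total = 0
    sp_total = 0
    for lin in lineages:
        if lineage_at(lin, "family") == family:
            fam_total += 1
            if lineage_at(lin, "species") == species:
                sp_total += 1
    if fam_total == 0:
        raise ValueError(f"no reads classified to family {family!r}")
    return sp_total / fam_total


def dominant_species_fraction(lineages, family: str) -> tuple:
    """The most abundant species within ``family`` and its fraction."""
    tallies: dict[str, int] = {}
    fam_total = 0
    for lin in lineages:
        if lineage_at(lin, "family") == family:
            fam_total += 1
            sp = lineage_at(lin, "species")
            if sp is not None:
                tallies[sp] = tallies.get(sp, 0) + 1
    if fam_total == 0:
        raise ValueError(f"no reads classified to family {family!r}")
    sp = max(sorted(tallies), key=lambda s: tallies[s])
    return sp, tallies[sp] / fam_total
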