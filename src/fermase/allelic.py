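"""Allele-specific expression from phased SNPs and LOH run detection.

Each aligned read overlapping a gene is compared to both haplotypes at the
phased heterozygous SNP positions it covers.  Unanimous support assigns the
read to haplotype 1 or 2; mixed support marks it conflicting; a read
covering no SNP is uninformative.  Counting is per read, per gene — a read
spanning several SNPs is counted once — so the gene-level record reflects
the cumulative imbalance across all its phased SNPs.

Differential allelic expression (DAE) is called at a 2-fold threshold
between alleles: a gene is monoallelically biased when the major allele
holds at least two thirds of its informative reads (ratio >= 2; exactly 2/3
qualifies, the prose gloss being "more than 66%").  A minimum informative
depth guards against calling imbalance from a handful of reads.

Runs of consecutive near-fully monoallelic genes with the same dominant
haplotype mark loss-of-heterozygosity (LOH) blocks; the detector tolerates
short interior stretches of uninformative (SNP-free or shallow) genes, the
analogue of a homozygous region where no allelic signal exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from fermase.align import STATUS_ALIGNED, AlignmentResult

#: allelic-ratio boundary: the major allele must hold >= 2/3 of informative reads
DAE_BOUNDARY_FRACTION = Fraction(2, 3)


def dae_boundary_percent() -> int:
    """The single-allele percentage at the exact 2-fold boundary (floor)."""
    return math.floor(100 * DAE_BOUNDARY_FRACTION)


@dataclass
class GeneModel:
    """A gene interval with its ordered phased heterozygous SNPs.

    SNPs are ``(position, h1_base, h2_base)`` with 1-based chromosome
    positions strictly increasing inside ``[start, end]``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    snps: list = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        last = None
        for pos, h1, h2 in self.snps:
            if not self.start <= pos <= self.end:
                raise ValueError(f"{self.gene_id}: SNP at {pos} outside gene")
            if last is not None and pos <= last:
                raise ValueError(f"{self.gene_id}: SNP positions not increasing")
            if h1 == h2:
                raise ValueError(f"{self.gene_id}: haplotype bases identical")
            last = pos

    @property
    def snp_offsets(self) -> list:
        """SNP positions relative to the gene start (0-based)."""
        return [pos - self.start for pos, _, _ in self.snps]


@dataclass
class AlleleCountRecord:
    gene_id: str
    condition: str
    reads_h1: int = 0
    reads_h2: int = 0
    reads_conflicting: int = 0

    @property
    def informative_depth(self) -> int:
        return self.reads_h1 + self.reads_h2


@dataclass
class DaeCall:
    gene_id: str
    condition: str
    reads_h1: int
    reads_h2: int
    allele1_fraction: float  # NaN when uninformative
    allelic_ratio: float  # max/min, inf when the minor count is 0
    call: str  # allele1 | allele2 | balanced | uninformative

    @property
    def is_dae(self) -> bool:
        return self.call in ("allele1", "allele2")

    @property
    def major_fraction(self) -> float:
        f = self.allele1_fraction
        return max(f, 1.0 - f) if not math.isnan(f) else math.nan


@dataclass
class LohSegment:
    chrom: str
    first_gene: str
    last_gene: str
    first_index: int  # order along the chromosome
    last_index: int
    gene_count: int  # monoallelic genes in the run
    span_bp: int  # first gene start to last gene end, inclusive
    dominant_haplotype: int


# ---------------------------------------------------------------------------
# per-read haplotype assignment


def assign_read_haplotype(read_seq: str, read_offset: int, gene: GeneModel) -> str:
    """Classify one aligned read as h1 / h2 / conflicting / uninformative.

    ``read_offset`` is the 0-based start of the read within the gene.  Bases
    at every covered SNP are compared with both haplotypes; a base matching
    neither haplotype counts as disagreement (sequencing error or a third
    allele) and makes the read conflicting.
    """
    votes = set()
    end = read_offset + len(read_seq)
    for (pos, h1, h2), off in zip(gene.snps, gene.snp_offsets):
        if read_offset <= off < end:
            base = read_seq[off - read_offset]
            if base == h1:
                votes.add("h1")
            elif base == h2:
                votes.add("h2")
            else:
                votes.add("mismatch")
    if not votes:
        return "uninformative"
    if votes == {"h1"}:
        return "h1"
    if votes == {"h2"}:
        return "h2"
    return "conflicting"


def accumulate_gene_alleles(
    aln: AlignmentResult,
    reads,
    genes,
    condition: str,
    existing: dict | None = None,
) -> dict:
    """Tally haplotype-supporting reads per gene from one aligned library.

    ``reads`` are the ``(id, seq)`` pairs that were aligned (same order as
    ``aln``); ``genes`` maps every alignable feature that is a gene to its
    :class:`GeneModel`.  Each read contributes at most one count to the gene
    it aligned to.  Pass ``existing`` to pool several libraries of the same
    condition into one record set.
    """
    records = existing if existing is not None else {}
    for g in genes.values():
        records.setdefault(
            g.gene_id, AlleleCountRecord(gene_id=g.gene_id, condition=condition)
        )
    name_of = aln.names
    aligned = np.flatnonzero(aln.status == STATUS_ALIGNED)
    for i in aligned:
        gene = genes.get(name_of[int(aln.feature[i])])
        if gene is None:
            continue
        verdict = assign_read_haplotype(reads[i][1], int(aln.offset[i]), gene)
        rec = records[gene.gene_id]
        if verdict == "h1":
            rec.reads_h1 += 1
        elif verdict == "h2":
            rec.reads_h2 += 1
        elif verdict == "conflicting":
            rec.reads_conflicting += 1
    return records


# ---------------------------------------------------------------------------
# DAE calling


def call_dae(record: AlleleCountRecord, min_depth: int = 20) -> DaeCall:
    """Apply the 2-fold allelic-imbalance rule to one gene record.

    Conflicting reads are excluded from informative depth.  The boundary is
    inclusive — exactly a 2:1 ratio (major fraction exactly 2/3) is called —
    and the comparison is done in integer arithmetic (``major >= 2 * minor``)
    so no floating-point edge can flip a boundary case.
    """
    h1, h2 = record.reads_h1, record.reads_h2
    depth = h1 + h2
    if depth < min_depth or depth == 0:
        return DaeCall(
            record.gene_id,
            record.condition,
            h1,
            h2,
            math.nan,
            math.nan,
            "uninformative",
        )
    frac1 = h1 / depth
    major, minor = max(h1, h2), min(h1, h2)
    ratio = math.inf if minor == 0 else major / minor
    if major >= 2 * minor and major > minor:
        call = "allele1" if h1 > h2 else "allele2"
    else:
        call = "balanced"
    return DaeCall(record.gene_id, record.condition, h1, h2, frac1, ratio, call)


def call_dae_table(records: dict, min_depth: int = 20) -> dict:
    return {gid: call_dae(rec, min_depth) for gid, rec in records.items()}


# ---------------------------------------------------------------------------
# LOH run detection


def _mono_status(call: DaeCall, mono_fraction: float):
    """'1'/'2' when near-fully monoallelic, 'u' uninformative, 'h' otherwise."""
    if call.call == "uninformative":
        return "u"
    if call.major_fraction >= mono_fraction:
        return "1" if call.allele1_fraction >= 0.5 else "2"
    return "h"


def detect_loh_runs(
    calls,
    genes,
    mono_fraction: float = 0.95,
    min_genes: int = 10,
    max_uninformative_gap: int = 2,
) -> list:
    """Maximal runs of same-haplotype monoallelic genes along one chromosome.

    ``calls`` and ``genes`` are parallel lists sorted by gene start
    coordinate (a single chromosome).  A run is extended over up to
    ``max_uninformative_gap`` consecutive uninformative genes; it must start
    and end on a monoallelic gene.  Runs with fewer than ``min_genes``
    monoallelic genes are discarded.  Returned segments are disjoint.
    """
    if len(calls) != len(genes):
        raise ValueError("calls and genes differ in length")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start coordinate")
    status = [_mono_status(c, mono_fraction) for c in calls]

    segments: list[LohSegment] = []
    i = 0
    n = len(status)
    while i < n:
        if status[i] not in ("1", "2"):
            i += 1
            continue
        dom = status[i]
        first = last = i
        count = 1
        gap = 0
        j = i + 1
        while j < n:
            s = status[j]
            if s == dom:
                last = j
                count += 1
                gap = 0
            elif s == "u" and gap < max_uninformative_gap:
                gap += 1
            else:
                break
            j += 1
        if count >= min_genes:
            segments.append(
                LohSegment(
                    chrom=genes[first].chrom,
                    first_gene=genes[first].gene_id,
                    last_gene=genes[last].gene_id,
                    first_index=first,
                    last_index=last,
                    gene_count=count,
                    span_bp=genes[last].end - genes[first].start + 1,
                    dominant_haplotype=int(dom),
                )
            )
        i = max(last + 1, i + 1)
    return segments


def exclude_region(calls: dict, genes: dict, chrom: str, from_position: int) -> dict:
    """Drop genes on ``chrom`` whose start is at or beyond ``from_position``."""
    return {
        gid: c
        for gid, c in calls.items()
        if not (
            genes[gid].chrom == chrom and genes[gid].start >= from_position
        )
    }


def compare_conditions(calls_a: dict, calls_b: dict) -> dict:
    """Partition DAE genes into both / A-only / B-only sets.

    A gene is DAE in a condition when its call there is allele1 or allele2.
    The two call sets must cover the same gene universe.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("condition call sets cover different gene universes")
    in_a = {g for g, c in calls_a.items() if c.is_dae}
    in_b = {g for g, c in calls_b.items() if c.is_dae}
    return {
        "both": in_a & in_b,
        "A_only": in_a - in_b,
        "B_only": in_b - in_a,
    }


# ---------------------------------------------------------------------------
# restriction-digest marker utility


def insilico_digest(
    sequence: str, recognition_site: str = "GATC", cut_offset: int = 0
) -> list:
    """Predict restriction fragment lengths for a blunt/offset cutter.

    Cuts immediately before each occurrence of the recognition site plus
    ``cut_offset`` (MboI cuts ^GATC, offset 0).  Fragment lengths always sum
    to the sequence length; a site destroyed by a SNP simply yields no cut,
    which is what makes the digest an allele genotyping assay.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not recognition_site:
        raise ValueError("empty recognition site")
    n = len(sequence)
    cuts = []
    start = sequence.find(recognition_site)
    while start != -1:
        cut = start + cut_offset
        if 0 < cut < n:
            cuts.append(cut)
        start = sequence.find(recognition_site, start + 1)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [n]
    return [bounds[k + 1] - bounds[k] for k in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# tabular views


def dae_table(calls: dict, genes: dict) -> pd.DataFrame:
    rows = []
    for gid in sorted(calls):
        c = calls[gid]
        g = genes[gid]
        rows.append(
            {
                "gene_id": gid,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "condition": c.condition,
                "reads_h1": c.reads_h1,
                "reads_h2": c.reads_h2,
                "allele1_fraction": c.allele1_fraction,
                "allelic_ratio": c.allelic_ratio,
                "call": c.call,
            }
        )
    return pd.DataFrame(rows)


def loh_table(segments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "first_gene": s.first_gene,
                "last_gene": s.last_gene,
                "gene_count": s.gene_count,
                "span_bp": s.span_bp,
                "dominant_haplotype": s.dominant_haplotype,
            }
            for s in segments
        ],
        columns=[
            "chrom",
            "first_gene",
            "last_gene",
            "gene_count",
            "span_bp",
            "dominant_haplotype",
        ],
    )
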