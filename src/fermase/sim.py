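"""Synthetic diploid transcriptome and read-set generator.

The generator emulates the statistical structure the downstream analyses
assume for a heterozygous diploid yeast sampled under two fermentation
conditions:

* genes laid along chromosomes with intergenic gaps, every gap longer than
  500 bp so each one qualifies for the genomic-background (RPKM threshold)
  set;
* phased heterozygous SNPs inside genes, two haplotype sequences per gene
  differing exactly at those SNPs;
* a planted contiguous block of monoallelic genes on one chromosome — a
  loss-of-heterozygosity (LOH) event — whose genomic span is a config field
  and is honoured exactly;
* gene sets with condition-specific allelic imbalance (default 3:1) in
  condition A only, condition B only, or both, all other genes balanced;
* a configurable fraction of reads drawn from intergenic regions
  (background transcription) and from a lineage-labelled bacterial rRNA
  reference (residual non-mRNA material in a poly-A selected library).

Reads are error-free, single-end and 36 bp by default.  All planted
compositions use exact largest-remainder allocation rather than multinomial
sampling, so preset compositions are hit exactly and recovered values are
stable across seeds.  Two named presets mirror the study's reported
architecture: ``paper_fig5`` (140-gene / 600-kb LOH block plus 55 shared,
61 A-only and 33 B-only imbalanced genes among ~1,500) and
``paper_fig1b_fl`` / ``paper_fig1b_tf`` (bacterial rRNA mixes whose
within-Lactobacillaceae *L. fermentum* fractions are exactly 93% and 41%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fermase.util import condition_seed, largest_remainder, split_two

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PlantedLoh:
    """A contiguous run of monoallelic genes planted on one chromosome."""

    chromosome: str
    gene_count: int
    span_bp: int
    dominant_haplotype: int = 1


@dataclass
class PlantedDae:
    """Counts (or explicit gene ids) of genes with planted allelic imbalance."""

    both: int | list = 0
    a_only: int | list = 0
    b_only: int | list = 0
    ratio: float = 3.0  # major:minor allele read ratio


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    genes_per_chromosome: int | list = 25
    gene_length_range: tuple = (500, 3000)
    snps_per_gene_range: tuple = (0, 8)
    intergenic_gap_range: tuple = (501, 4600)
    read_length_bp: int = 36
    reads_per_library: int = 20000
    informative_depth: int = 100  # SNP-overlapping reads per gene per library
    planted_loh: PlantedLoh | None = None
    planted_dae: PlantedDae | None = None
    intergenic_background_rate: float = 0.0
    rrna_mix: dict = field(default_factory=dict)
    rrna_ref_length_bp: int = 150
    conditions: tuple = ("TF", "FL")
    seed: int = 42

    def genes_per_chrom_list(self) -> list[int]:
        g = self.genes_per_chromosome
        if isinstance(g, int):
            return [g] * self.n_chromosomes
        if len(g) != self.n_chromosomes:
            raise ValueError("genes_per_chromosome length != n_chromosomes")
        return list(g)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if any(n < 1 for n in self.genes_per_chrom_list()):
            raise ValueError("every chromosome needs at least one gene")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad gene_length_range")
        if self.read_length_bp > lo:
            raise ValueError("read_length_bp exceeds the minimum gene length")
        slo, shi = self.snps_per_gene_range
        if slo < 0 or shi < slo:
            raise ValueError("bad snps_per_gene_range")
        if shi > lo:
            raise ValueError("SNP count may exceed gene length")
        glo, ghi = self.intergenic_gap_range
        if not (500 < glo <= ghi):
            raise ValueError("intergenic gaps must exceed 500 bp")
        if not 0.0 <= self.intergenic_background_rate <= 1.0:
            raise ValueError("intergenic_background_rate outside [0, 1]")
        for lin, f in self.rrna_mix.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"rrna_mix fraction for {lin!r} outside [0, 1]")
        tot = sum(self.rrna_mix.values())
        if tot > 1.0 + 1e-9:
            raise ValueError("rrna_mix fractions sum to more than 1")
        if tot + self.intergenic_background_rate >= 1.0:
            raise ValueError("no read budget left for genes")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct condition labels required")
        if self.planted_loh is not None:
            loh = self.planted_loh
            if loh.chromosome not in self.chrom_names():
                raise ValueError(f"unknown LOH chromosome {loh.chromosome!r}")
            idx = self.chrom_names().index(loh.chromosome)
            if loh.gene_count > self.genes_per_chrom_list()[idx]:
                raise ValueError("LOH block larger than its chromosome")
            if loh.dominant_haplotype not in (1, 2):
                raise ValueError("dominant haplotype must be 1 or 2")
        if self.planted_dae is not None:
            for part in ("both", "a_only", "b_only"):
                v = getattr(self.planted_dae, part)
                if isinstance(v, int) and v < 0:
                    raise ValueError("negative planted DAE count")
            if self.planted_dae.ratio < 1.0:
                raise ValueError("DAE ratio must be >= 1")


# ---------------------------------------------------------------------------
# reference bundle


@dataclass
class Snp:
    offset: int  # 0-based within the gene
    h1: str
    h2: str


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive chromosome coordinates
    end: int
    seq1: str
    seq2: str
    snps: list
    dae_class: str = "balanced"  # balanced | both | a_only | b_only | loh
    frac: dict = field(default_factory=dict)  # condition -> allele-1 fraction

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        return self.dae_class == "loh"


@dataclass
class IntergenicRecord:
    region_id: str
    chrom: str
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RrnaRecord:
    ref_id: str
    lineage: str
    seq: str


@dataclass
class ReferenceBundle:
    config: SimConfig
    genes: list
    intergenic: list
    rrna: list

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_lookup()[gene_id]

    def _gene_lookup(self):
        if not hasattr(self, "_lookup"):
            self._lookup = {g.gene_id: g for g in self.genes}
        return self._lookup

    def gene_truth(self) -> pd.DataFrame:
        """Per-gene ground truth: class, LOH flag, allele-1 fraction per condition."""
        ca, cb = self.config.conditions
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "length": g.length,
                "n_snps": len(g.snps),
                "dae_class": g.dae_class,
                "loh": g.is_loh,
                f"frac1_{ca}": g.frac[ca],
                f"frac1_{cb}": g.frac[cb],
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        """Write the bundle as FASTA/GFF3/VCF/TSV files; return the paths."""
        from fermase import io as fio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_fasta": outdir / "genes_hap1.fasta",
            "genes_hap2_fasta": outdir / "genes_hap2.fasta",
            "gff3": outdir / "genes.gff3",
            "intergenic_fasta": outdir / "intergenic.fasta",
            "vcf": outdir / "snps.vcf",
            "gene_truth": outdir / "gene_truth.tsv",
        }
        fio.write_fasta(
            ((g.gene_id, g.seq1) for g in self.genes), paths["genes_fasta"]
        )
        fio.write_fasta(
            ((g.gene_id, g.seq2) for g in self.genes), paths["genes_hap2_fasta"]
        )
        fio.write_gff3(self.genes, paths["gff3"])
        fio.write_fasta(
            ((r.region_id, r.seq) for r in self.intergenic),
            paths["intergenic_fasta"],
        )
        fio.write_phased_vcf(self.genes, self.config.chrom_names(), paths["vcf"])
        self.gene_truth().to_csv(paths["gene_truth"], sep="\t", index=False)
        if self.rrna:
            paths["rrna_fasta"] = outdir / "rrna.fasta"
            fio.write_fasta(
                ((f"{r.ref_id} {r.lineage}", r.seq) for r in self.rrna),
                paths["rrna_fasta"],
            )
        return paths


def _random_seq(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _snp_offsets(rng, gene_len: int, n: int, spacing: int) -> list[int]:
    """n positions in [0, gene_len) pairwise >= spacing apart (sorted)."""
    if n == 0:
        return []
    room = gene_len - (n - 1) * spacing
    if room <= 0:
        raise ValueError("gene too short for requested SNP spacing")
    u = np.sort(rng.choice(room, size=n, replace=False))
    return [int(u[i] + i * spacing) for i in range(n)]


def _block_gaps(rng, lengths, span_bp: int, gap_lo: int, gap_hi: int):
    """Gaps between LOH-block genes rescaled so the block spans span_bp exactly."""
    b = len(lengths)
    gsum = span_bp - int(np.sum(lengths))
    if b == 1:
        if gsum != 0:
            raise ValueError("single-gene LOH block cannot match span")
        return []
    if gsum < (b - 1) * gap_lo:
        raise ValueError("LOH span too small for its gene count")
    raw = rng.integers(gap_lo, gap_hi + 1, b - 1).astype(float)
    gaps = np.maximum(gap_lo, np.round(raw * gsum / raw.sum()).astype(int))
    # push the rounding residue onto the widest gap
    gaps[int(np.argmax(gaps))] += gsum - int(gaps.sum())
    if gaps.min() < gap_lo:
        raise ValueError("LOH span incompatible with minimum gap")
    return [int(g) for g in gaps]


def build_reference(config: SimConfig) -> ReferenceBundle:
    """Deterministically build the reference bundle for ``config``.

    The same config (including its seed) always yields an identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.read_length_bp
    glo, ghi = config.gene_length_range
    gap_lo, gap_hi = config.intergenic_gap_range
    slo, shi = config.snps_per_gene_range
    loh = config.planted_loh

    genes: list[GeneRecord] = []
    intergenic: list[IntergenicRecord] = []
    gi = 0
    for chrom, n_genes in zip(config.chrom_names(), config.genes_per_chrom_list()):
        lengths = rng.integers(glo, ghi + 1, n_genes)
        gaps = rng.integers(gap_lo, gap_hi + 1, n_genes)  # gap before each gene
        block_first = None
        if loh is not None and chrom == loh.chromosome:
            # the block occupies the last gene_count genes (the "right arm")
            block_first = n_genes - loh.gene_count
            inner = _block_gaps(
                rng, lengths[block_first:], loh.span_bp, gap_lo, gap_hi
            )
            for j, g in enumerate(inner):
                gaps[block_first + 1 + j] = g
        pos = 0
        for i in range(n_genes):
            gap = int(gaps[i])
            ig_start = pos + 1
            ig_end = pos + gap
            intergenic.append(
                IntergenicRecord(
                    region_id=f"ig_{chrom}_{i:04d}",
                    chrom=chrom,
                    start=ig_start,
                    end=ig_end,
                    seq=_random_seq(rng, gap),
                )
            )
            start = ig_end + 1
            gene_len = int(lengths[i])
            n_snps = min(
                int(rng.integers(slo, shi + 1)), (gene_len - 1) // L + 1
            )
            offsets = _snp_offsets(rng, gene_len, n_snps, spacing=L)
            seq1 = _random_seq(rng, gene_len)
            snps = []
            s2 = bytearray(seq1, "ascii")
            for off in offsets:
                h1 = seq1[off]
                others = [b for b in "ACGT" if b != h1]
                h2 = others[int(rng.integers(0, 3))]
                s2[off] = ord(h2)
                snps.append(Snp(offset=off, h1=h1, h2=h2))
            gi += 1
            rec = GeneRecord(
                gene_id=f"g{gi:05d}",
                chrom=chrom,
                start=start,
                end=start + gene_len - 1,
                seq1=seq1,
                seq2=s2.decode("ascii"),
                snps=snps,
            )
            if block_first is not None and i >= block_first:
                rec.dae_class = "loh"
            genes.append(rec)
            pos = rec.end

    _assign_dae(rng, genes, config)

    rrna = []
    for i, lineage in enumerate(sorted(config.rrna_mix)):
        rrna.append(
            RrnaRecord(
                ref_id=f"rrna_{i:03d}",
                lineage=lineage,
                seq=_random_seq(rng, config.rrna_ref_length_bp),
            )
        )
    return ReferenceBundle(
        config=config, genes=genes, intergenic=intergenic, rrna=rrna
    )


def _assign_dae(rng, genes, config: SimConfig) -> None:
    """Pick planted-imbalance genes and set per-condition allele-1 fractions."""
    ca, cb = config.conditions
    dae = config.planted_dae or PlantedDae()
    loh_chrom = config.planted_loh.chromosome if config.planted_loh else None
    by_id = {g.gene_id: g for g in genes}

    def resolve(v, pool, k_taken):
        if isinstance(v, int):
            take = pool[k_taken : k_taken + v]
            if len(take) < v:
                raise ValueError("not enough eligible genes for planted DAE sets")
            return list(take), k_taken + v
        ids = list(v)
        for gid in ids:
            if gid not in by_id:
                raise ValueError(f"unknown planted gene id {gid!r}")
        return ids, k_taken

    # eligible pool: off the LOH chromosome entirely, so the planted sets stay
    # disjoint from the block and survive right-arm exclusion
    eligible = [g.gene_id for g in genes if g.chrom != loh_chrom and g.snps]
    perm = [eligible[i] for i in rng.permutation(len(eligible))]
    k = 0
    sets = {}
    for part in ("both", "a_only", "b_only"):
        sets[part], k = resolve(getattr(dae, part), perm, k)
    all_ids = sets["both"] + sets["a_only"] + sets["b_only"]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("planted DAE gene sets overlap")
    if config.planted_loh is not None:
        block = {g.gene_id for g in genes if g.dae_class == "loh"}
        if block & set(all_ids):
            raise ValueError("planted DAE genes overlap the LOH block")

    p = dae.ratio / (dae.ratio + 1.0)
    for part, ids in sets.items():
        for j, gid in enumerate(ids):
            g = by_id[gid]
            g.dae_class = part
            major1 = j % 2 == 0  # alternate the favoured haplotype
            hi = p if major1 else 1.0 - p
            g.frac = {
                ca: hi if part in ("both", "a_only") else 0.5,
                cb: hi if part in ("both", "b_only") else 0.5,
            }
    for g in genes:
        if g.dae_class == "loh":
            f = 1.0 if config.planted_loh.dominant_haplotype == 1 else 0.0
            g.frac = {ca: f, cb: f}
        elif not g.frac:
            g.frac = {ca: 0.5, cb: 0.5}


# ---------------------------------------------------------------------------
# read simulation


def _allowed_background_starts(gene_len: int, L: int, offsets):
    """Intervals of read starts whose window covers no SNP, as (lo, hi) incl."""
    intervals = []
    cur = 0
    for p in offsets:
        lo_forbidden = max(0, p - L + 1)
        if lo_forbidden - 1 >= cur:
            intervals.append((cur, lo_forbidden - 1))
        cur = p + 1
    if gene_len - L >= cur:
        intervals.append((cur, gene_len - L))
    return intervals


def simulate_library(
    bundle: ReferenceBundle,
    config: SimConfig,
    condition: str,
    fastq_path=None,
    truth_path=None,
):
    """Simulate one library for ``condition``; return (reads, truth table).

    ``reads`` is a list of ``(read_id, sequence)``; the truth table is a
    DataFrame with one row per read (source, feature, haplotype, lineage).
    Reads are error-free.  Informative (SNP-overlapping) reads are planted at
    ``config.informative_depth`` per gene and split between haplotypes by
    exact rounding of the gene's true allele-1 fraction for the condition;
    remaining gene reads avoid SNP windows so observed allele counts are
    exactly the planted ones.
    """
    if condition not in config.conditions:
        raise ValueError(
            f"condition {condition!r} not in configured conditions "
            f"{config.conditions}"
        )
    rng = np.random.default_rng(condition_seed(config.seed, condition))
    L = config.read_length_bp
    N = config.reads_per_library

    lineages = sorted(config.rrna_mix)
    rrna_counts = [
        int(np.floor(config.rrna_mix[lin] * N + 0.5)) for lin in lineages
    ]
    n_ig = int(np.floor(config.intergenic_background_rate * N + 0.5))
    gene_total = N - sum(rrna_counts) - n_ig
    if gene_total < 0:
        raise ValueError("rRNA + intergenic fractions exceed the read budget")
    n_genes = len(bundle.genes)
    per_gene = largest_remainder(gene_total, np.ones(n_genes))

    seqs: list[str] = []
    src: list[str] = []
    feat: list[str] = []
    hap: list[int] = []
    lin_col: list[str] = []

    for g, n_g in zip(bundle.genes, per_gene):
        n_g = int(n_g)
        if n_g == 0:
            continue
        n_inf = min(config.informative_depth, n_g) if g.snps else 0
        n_bg = n_g - n_inf
        frac1 = g.frac[condition]
        if n_inf:
            n_h1, n_h2 = split_two(n_inf, frac1)
            offs = np.array([s.offset for s in g.snps])
            which = np.arange(n_inf) % len(offs)
            p = offs[which]
            lo = np.maximum(0, p - L + 1)
            hi = np.minimum(p, g.length - L)
            starts = rng.integers(lo, hi + 1)
            haps = np.concatenate(
                [np.ones(n_h1, dtype=int), np.full(n_h2, 2, dtype=int)]
            )
            for st, h in zip(starts, haps):
                seq = g.seq1 if h == 1 else g.seq2
                seqs.append(seq[st : st + L])
                src.append("gene")
                feat.append(g.gene_id)
                hap.append(int(h))
                lin_col.append("")
        if n_bg:
            intervals = _allowed_background_starts(
                g.length, L, [s.offset for s in g.snps]
            )
            if intervals:
                sizes = np.array([b - a + 1 for a, b in intervals])
                cum = np.cumsum(sizes)
                draws = rng.integers(0, cum[-1], n_bg)
                for d in draws:
                    k = int(np.searchsorted(cum, d, side="right"))
                    st = intervals[k][0] + int(d) - (int(cum[k - 1]) if k else 0)
                    seqs.append(g.seq1[st : st + L])
                    src.append("gene")
                    feat.append(g.gene_id)
                    hap.append(0)
                    lin_col.append("")
            else:  # degenerate: SNPs everywhere, fall back to sampled haplotypes
                for _ in range(n_bg):
                    h = 1 if rng.random() < frac1 else 2
                    st = int(rng.integers(0, g.length - L + 1))
                    seq = g.seq1 if h == 1 else g.seq2
                    seqs.append(seq[st : st + L])
                    src.append("gene")
                    feat.append(g.gene_id)
                    hap.append(h)
                    lin_col.append("")

    if n_ig:
        ridx = rng.integers(0, len(bundle.intergenic), n_ig)
        for k in ridx:
            r = bundle.intergenic[int(k)]
            st = int(rng.integers(0, r.length - L + 1))
            seqs.append(r.seq[st : st + L])
            src.append("intergenic")
            feat.append(r.region_id)
            hap.append(0)
            lin_col.append("")

    rrna_by_lineage = {r.lineage: r for r in bundle.rrna}
    for lineage, cnt in zip(lineages, rrna_counts):
        r = rrna_by_lineage[lineage]
        starts = rng.integers(0, len(r.seq) - L + 1, cnt)
        for st in starts:
            seqs.append(r.seq[int(st) : int(st) + L])
            src.append("rrna")
            feat.append(r.ref_id)
            hap.append(0)
            lin_col.append(lineage)

    order = rng.permutation(len(seqs))
    ids = [f"{condition}_r{i + 1:07d}" for i in range(len(seqs))]
    reads = [(ids[j], seqs[int(i)]) for j, i in enumerate(order)]
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "source": [src[int(i)] for i in order],
            "feature_id": [feat[int(i)] for i in order],
            "haplotype": [hap[int(i)] for i in order],
            "lineage": [lin_col[int(i)] for i in order],
        }
    )
    truth["condition"] = condition

    if fastq_path is not None:
        from fermase import io as fio

        fio.write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth


# ---------------------------------------------------------------------------
# presets

_LACTO = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus"
_ACETO = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;"
    "Acetobacteraceae;Acetobacter;Acetobacter pasteurianus"
)
_BACIL = "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus subtilis"

# family-level envelopes are modelling choices; the within-Lactobacillaceae
# L. fermentum shares (93% and 41%) are the study's reported values
_FIG1B_FL_MIX = {
    f"{_LACTO};Lactobacillus fermentum": 0.2790,  # 5580 of 6000 family reads
    f"{_LACTO};Lactobacillus vini": 0.0150,
    f"{_LACTO};Lactobacillus plantarum": 0.0060,
    _ACETO: 0.1250,
    _BACIL: 0.0750,
}
_FIG1B_TF_MIX = {
    f"{_LACTO};Lactobacillus fermentum": 0.1025,  # 2050 of 5000 family reads
    f"{_LACTO};Lactobacillus vini": 0.0875,
    f"{_LACTO};Lactobacillus plantarum": 0.0600,
    _ACETO: 0.1500,
    _BACIL: 0.1000,
}

PRESET_NAMES = ("smoke", "paper_fig5", "paper_fig1b_fl", "paper_fig1b_tf")


def preset(name: str) -> SimConfig:
    """Return a named, fully specified :class:`SimConfig`."""
    if name == "smoke":
        cfg = SimConfig(
            n_chromosomes=2,
            genes_per_chromosome=25,
            gene_length_range=(500, 1500),
            snps_per_gene_range=(1, 3),
            intergenic_gap_range=(501, 2000),
            reads_per_library=4500,
            informative_depth=40,
            planted_loh=PlantedLoh("chr02", gene_count=12, span_bp=24000),
            planted_dae=PlantedDae(both=3, a_only=2, b_only=2),
            intergenic_background_rate=0.02,
            seed=42,
        )
    elif name == "paper_fig5":
        gpc = [90] * 16
        gpc[12] = 160  # chr13 carries the 140-gene block on its right arm
        cfg = SimConfig(
            n_chromosomes=16,
            genes_per_chromosome=gpc,
            gene_length_range=(500, 3000),
            snps_per_gene_range=(1, 4),
            intergenic_gap_range=(501, 4600),
            reads_per_library=323400,
            informative_depth=200,
            planted_loh=PlantedLoh("chr13", gene_count=140, span_bp=600000),
            planted_dae=PlantedDae(both=55, a_only=61, b_only=33, ratio=3.0),
            intergenic_background_rate=0.01,
            seed=42,
        )
    elif name in ("paper_fig1b_fl", "paper_fig1b_tf"):
        cfg = SimConfig(
            n_chromosomes=2,
            genes_per_chromosome=25,
            gene_length_range=(500, 1500),
            snps_per_gene_range=(0, 2),
            intergenic_gap_range=(501, 2000),
            reads_per_library=20000,
            informative_depth=20,
            intergenic_background_rate=0.02,
            rrna_mix=dict(
                _FIG1B_FL_MIX if name.endswith("fl") else _FIG1B_TF_MIX
            ),
            seed=42,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg.validate()
    return cfg


def preset_with_seed(name: str, seed: int) -> SimConfig:
    return replace(preset(name), seed=int(seed) % (2**31))
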