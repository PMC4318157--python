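"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, FASTQ via Biopython's fast tuple iterator (written as
plain records with constant quality — the simulator is error-free), GFF3
via gffutils, VCF via pysam.  TSV tables are pandas with ``#``-comment
header lines that echo the parameters used to produce them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records, path) -> None:
    """Write ``(name, seq)`` pairs; the name may include a description."""
    recs = []
    for name, seq in records:
        parts = str(name).split(None, 1)
        recs.append(
            SeqRecord(
                Seq(seq),
                id=parts[0],
                description=parts[1] if len(parts) > 1 else "",
            )
        )
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    """Return ``{record id: sequence}`` (descriptions dropped)."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_fasta_with_descriptions(path) -> list:
    """Return ``[(id, description, sequence)]`` in file order."""
    return [
        (rec.id, rec.description.partition(" ")[2], str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(fh)]


def write_gff3(genes, path) -> None:
    """1-based inclusive coordinates, unstranded genes reported on '+'."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tfermase\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_genes_gff3(path) -> pd.DataFrame:
    """Gene intervals from a GFF3 file (gene_id, chrom, start, end)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    rows = [
        {
            "gene_id": feat.id,
            "chrom": feat.seqid,
            "start": feat.start,
            "end": feat.end,
        }
        for feat in db.features_of_type("gene", order_by=("seqid", "start"))
    ]
    return pd.DataFrame(rows)


def write_phased_vcf(genes, chrom_names, path) -> None:
    """Phased heterozygous SNPs, one record per SNP, GT ``0|1``.

    Haplotype 1 is the REF column (the alignment reference); haplotype 2 is
    ALT.  Coordinates are chromosome-level and 1-based.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    used = {g.chrom for g in genes}
    lengths = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    for c in chrom_names:
        if c in used:
            header.contigs.add(c, length=lengths[c] + 1)
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for g in genes:
            for s in g.snps:
                rec = vcf.new_record(
                    contig=g.chrom,
                    start=g.start + s.offset - 1,  # pysam start is 0-based
                    alleles=(s.h1, s.h2),
                )
                rec.samples["sample"]["GT"] = (0, 1)
                rec.samples["sample"].phased = True
                vcf.write(rec)


def read_phased_snps(path) -> pd.DataFrame:
    """Phased het SNPs as (chrom, pos, h1, h2); requires GT 0|1 or 1|0."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf:
            if len(rec.alleles) != 2:
                continue
            h1, h2 = rec.alleles
            if sample is not None:
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or set(gt) != {0, 1} or not call.phased:
                    continue
                if gt == (1, 0):
                    h1, h2 = h2, h1
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "h1": h1, "h2": h2}
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "h1", "h2"])


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with ``# key=value`` comment lines echoing parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
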