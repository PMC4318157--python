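"""End-to-end workflows tying the stages together.

The in-memory workflow functions are the single source of truth for how the
stages compose (simulate -> align -> count/RPKM/threshold -> DE -> allelic
-> LOH -> taxa); the command-line interface and the analysis drivers are
thin wrappers over them, so tests, scripts and the CLI all execute the same
code path.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from fermase import allelic, de, quant, sim, taxonomy
from fermase.align import FeatureIndex

log = logging.getLogger("fermase")


def configure_logging(logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s [%(name)s] %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# building blocks


def gene_models(bundle: sim.ReferenceBundle) -> dict:
    """GeneModel per gene (chromosome coordinates, phased SNP bases)."""
    out = {}
    for g in bundle.genes:
        out[g.gene_id] = allelic.GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            snps=[(g.start + s.offset, s.h1, s.h2) for s in g.snps],
        )
    return out


def reference_index(bundle: sim.ReferenceBundle, k: int = 12) -> FeatureIndex:
    """One matcher index over gene (haplotype 1) and intergenic features."""
    names = [g.gene_id for g in bundle.genes] + [
        r.region_id for r in bundle.intergenic
    ]
    seqs = [g.seq1 for g in bundle.genes] + [r.seq for r in bundle.intergenic]
    return FeatureIndex(names, seqs, k=k)


@dataclass
class LibraryRun:
    """Everything derived from one simulated, aligned library."""

    condition: str
    reads: list
    truth: pd.DataFrame
    aln: object
    counts: quant.LibraryCounts
    rpkm: pd.Series
    intergenic_rpkm: pd.Series
    threshold: quant.BackgroundThreshold
    allele_records: dict


def process_library(
    bundle: sim.ReferenceBundle,
    config: sim.SimConfig,
    condition: str,
    index: FeatureIndex,
    models: dict,
    max_mismatches: int = 2,
    quantile: float = 0.95,
) -> LibraryRun:
    reads, truth = sim.simulate_library(bundle, config, condition)
    aln = index.align(reads, max_mismatches=max_mismatches)
    gene_ids = [g.gene_id for g in bundle.genes]
    ig_ids = [r.region_id for r in bundle.intergenic]
    counts = quant.count_per_gene(aln, gene_ids, ig_ids, library_id=condition)
    lengths = pd.Series(
        {g.gene_id: g.length for g in bundle.genes}, name="length"
    )
    ig_lengths = pd.Series({r.region_id: r.length for r in bundle.intergenic})
    gene_rpkm = quant.rpkm(counts.gene_counts, lengths, counts.n_aligned_genes)
    ig_rpkm = quant.rpkm(
        counts.intergenic_counts, ig_lengths, counts.n_aligned_genes
    )
    threshold = quant.estimate_background_threshold(
        ig_rpkm.to_numpy(), quantile=quantile, library_id=condition
    )
    records = allelic.accumulate_gene_alleles(aln, reads, models, condition)
    log.info(
        "library %s: %d reads, %d aligned, %d repeat, %d unaligned, "
        "threshold RPKM %.3f",
        condition,
        len(reads),
        aln.n_aligned,
        aln.n_repeat,
        aln.n_unaligned,
        threshold.threshold,
    )
    return LibraryRun(
        condition=condition,
        reads=reads,
        truth=truth,
        aln=aln,
        counts=counts,
        rpkm=gene_rpkm,
        intergenic_rpkm=ig_rpkm,
        threshold=threshold,
        allele_records=records,
    )


# ---------------------------------------------------------------------------
# allelic workflow (the study's DAE/LOH analysis on a preset)


def run_allelic_workflow(
    config: sim.SimConfig,
    min_depth: int = 20,
    mono_fraction: float = 0.95,
    min_genes: int = 10,
    max_uninformative_gap: int = 2,
    max_mismatches: int = 2,
) -> dict:
    """Simulate both conditions and run the full DAE/LOH comparison.

    Returns a dict with the per-condition DAE calls, the condition Venn
    before and after excluding the detected LOH region, and the detected
    LOH segments (from pooled informative reads of both conditions).
    """
    bundle = sim.build_reference(config)
    index = reference_index(bundle)
    models = gene_models(bundle)
    cond_a, cond_b = config.conditions
    runs = {
        c: process_library(
            bundle, config, c, index, models, max_mismatches=max_mismatches
        )
        for c in config.conditions
    }
    calls = {
        c: allelic.call_dae_table(runs[c].allele_records, min_depth=min_depth)
        for c in config.conditions
    }
    venn = allelic.compare_conditions(calls[cond_a], calls[cond_b])

    # pool conditions for run detection: LOH is a genome property, not a
    # condition response, so both libraries inform the same segments
    pooled: dict = {}
    for c in config.conditions:
        for gid, rec in runs[c].allele_records.items():
            agg = pooled.setdefault(
                gid, allelic.AlleleCountRecord(gene_id=gid, condition="pooled")
            )
            agg.reads_h1 += rec.reads_h1
            agg.reads_h2 += rec.reads_h2
            agg.reads_conflicting += rec.reads_conflicting
    pooled_calls = allelic.call_dae_table(pooled, min_depth=min_depth)

    segments = []
    by_chrom: dict[str, list] = {}
    for g in bundle.genes:
        by_chrom.setdefault(g.chrom, []).append(g.gene_id)
    for chrom, gids in by_chrom.items():
        gids = sorted(gids, key=lambda gid: models[gid].start)
        segs = allelic.detect_loh_runs(
            [pooled_calls[gid] for gid in gids],
            [models[gid] for gid in gids],
            mono_fraction=mono_fraction,
            min_genes=min_genes,
            max_uninformative_gap=max_uninformative_gap,
        )
        segments.extend(segs)

    longest = max(segments, key=lambda s: s.gene_count, default=None)
    venn_excluded = venn
    if longest is not None:
        from_pos = models[longest.first_gene].start
        ex_a = allelic.exclude_region(
            calls[cond_a], models, longest.chrom, from_pos
        )
        ex_b = allelic.exclude_region(
            calls[cond_b], models, longest.chrom, from_pos
        )
        venn_excluded = allelic.compare_conditions(ex_a, ex_b)

    return {
        "bundle": bundle,
        "models": models,
        "runs": runs,
        "calls": calls,
        "venn": venn,
        "venn_excluded": venn_excluded,
        "segments": segments,
        "longest_segment": longest,
        "conditions": (cond_a, cond_b),
    }


# ---------------------------------------------------------------------------
# taxonomy workflow (residual rRNA profiling on a preset)


def run_taxonomy_workflow(
    config: sim.SimConfig,
    condition: str | None = None,
    max_mismatches: int = 2,
    family_cutoff: float = 0.05,
    strict: bool = False,
) -> dict:
    """Simulate one library and profile its non-gene reads against rRNA.

    Reads are first aligned to the gene/intergenic reference; only reads
    that fail that alignment are offered to the rRNA classifier, mirroring
    the sequential accounting of the original analysis.
    """
    bundle = sim.build_reference(config)
    condition = condition or config.conditions[0]
    index = reference_index(bundle)
    reads, truth = sim.simulate_library(bundle, config, condition)
    aln = index.align(reads, max_mismatches=max_mismatches)
    leftovers = [
        reads[i]
        for i in range(len(reads))
        if aln.status[i] != 1  # not uniquely aligned to the yeast reference
    ]
    rindex = taxonomy.build_rrna_index(
        [(r.ref_id, r.lineage, r.seq) for r in bundle.rrna]
    )
    lineages = taxonomy.classify_reads(
        leftovers, rindex, max_mismatches=max_mismatches, strict=strict
    )
    families = taxonomy.counts_per_taxon(lineages, "family")
    retained = taxonomy.apply_family_cutoff(families, min_fraction=family_cutoff)
    species = taxonomy.counts_per_taxon(lineages, "species")
    log.info(
        "taxa %s: %d candidate reads, %d classified, %d families retained",
        condition,
        len(leftovers),
        sum(1 for lin in lineages if lin),
        len(retained[retained["taxon"] != "unresolved"]),
    )
    return {
        "bundle": bundle,
        "condition": condition,
        "truth": truth,
        "n_candidate_reads": len(leftovers),
        "lineages": lineages,
        "family_counts": families,
        "family_retained": retained,
        "species_counts": species,
    }


# ---------------------------------------------------------------------------
# full pipeline with file outputs (used by the CLI)


@dataclass
class RunConfig:
    preset: str = "smoke"
    outdir: str = "fermase_run"
    seed: int | None = None
    max_mismatches: int = 2
    quantile: float = 0.95
    alpha: float = 0.01
    min_ratio: float = 2.0
    min_depth: int = 20
    mono_fraction: float = 0.95
    min_genes: int = 10
    max_uninformative_gap: int = 2
    family_cutoff: float = 0.05
    strict_ties: bool = False
    write_fastq: bool = False
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in known}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def params(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "extra"
        }
        return d


def run_pipeline(rc: RunConfig) -> dict:
    """Execute every stage for a preset and write TSV outputs + a report."""
    from fermase import io as fio

    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging(outdir / "run.log")
    config = sim.preset(rc.preset)
    if rc.seed is not None:
        config = sim.preset_with_seed(rc.preset, rc.seed)
    log.info("pipeline start: preset=%s seed=%d", rc.preset, config.seed)
    params = rc.params() | {"config_seed": config.seed}

    result = run_allelic_workflow(
        config,
        min_depth=rc.min_depth,
        mono_fraction=rc.mono_fraction,
        min_genes=rc.min_genes,
        max_uninformative_gap=rc.max_uninformative_gap,
        max_mismatches=rc.max_mismatches,
    )
    bundle = result["bundle"]
    models = result["models"]
    cond_a, cond_b = result["conditions"]
    runs = result["runs"]
    bundle.write(outdir / "reference")
    if rc.write_fastq:
        for c, lr in runs.items():
            fio.write_fastq(lr.reads, outdir / f"reads_{c}.fastq")
            lr.truth.to_csv(outdir / f"truth_{c}.tsv", sep="\t", index=False)

    # expression tables
    lengths = pd.Series({g.gene_id: g.length for g in bundle.genes})
    counts_df = pd.DataFrame(
        {c: runs[c].counts.gene_counts for c in (cond_a, cond_b)}
    )
    rpkm_df = pd.DataFrame({c: runs[c].rpkm for c in (cond_a, cond_b)})
    thresholds = {c: runs[c].threshold for c in (cond_a, cond_b)}
    expressed = quant.filter_expressed(rpkm_df, thresholds)
    fio.write_tsv(
        counts_df.rename_axis("gene_id").reset_index(),
        outdir / "counts.tsv",
        params,
    )
    fio.write_tsv(
        rpkm_df.rename_axis("gene_id").reset_index(), outdir / "rpkm.tsv", params
    )
    thr_df = pd.DataFrame(
        [
            {
                "library_id": t.library_id,
                "rpkm_threshold": t.threshold,
                "quantile": t.quantile,
                "expressed_genes": int(expressed[c].sum()),
            }
            for c, t in thresholds.items()
        ]
    )
    fio.write_tsv(thr_df, outdir / "thresholds.tsv", params)

    # two-library DE between the condition libraries
    de_table = de.de_two_library(
        counts_df[cond_a],
        runs[cond_a].counts.n_aligned_genes,
        counts_df[cond_b],
        runs[cond_b].counts.n_aligned_genes,
        alpha=rc.alpha,
        min_ratio=rc.min_ratio,
        expressed1=expressed[cond_a].to_numpy(),
        expressed2=expressed[cond_b].to_numpy(),
    )
    de_summary = de.tabulate_de(de_table)
    fio.write_tsv(de_table.reset_index(), outdir / "de.tsv", params)

    # allelic outputs
    for c in (cond_a, cond_b):
        fio.write_tsv(
            allelic.dae_table(result["calls"][c], models),
            outdir / f"dae_{c}.tsv",
            params,
        )
    fio.write_tsv(
        allelic.loh_table(result["segments"]), outdir / "loh_segments.tsv", params
    )
    venn = result["venn"]
    venn_ex = result["venn_excluded"]
    venn_df = pd.DataFrame(
        [
            {
                "scope": scope,
                "both": len(v["both"]),
                "A_only": len(v["A_only"]),
                "B_only": len(v["B_only"]),
            }
            for scope, v in (
                ("all_genes", venn),
                ("loh_region_excluded", venn_ex),
            )
        ]
    )
    fio.write_tsv(venn_df, outdir / "dae_venn.tsv", params)

    # taxonomy (only when the preset plants an rRNA admixture)
    taxa = None
    if config.rrna_mix:
        taxa = run_taxonomy_workflow(
            config,
            family_cutoff=rc.family_cutoff,
            strict=rc.strict_ties,
            max_mismatches=rc.max_mismatches,
        )
        fio.write_tsv(taxa["family_retained"], outdir / "taxa_families.tsv", params)
        fio.write_tsv(taxa["species_counts"], outdir / "taxa_species.tsv", params)

    summary = {
        "preset": rc.preset,
        "seed": config.seed,
        "n_genes": len(bundle.genes),
        "reads_per_library": config.reads_per_library,
        "expressed": {c: int(expressed[c].sum()) for c in (cond_a, cond_b)},
        "thresholds": {c: thresholds[c].threshold for c in (cond_a, cond_b)},
        "de": de_summary,
        "venn": {k: len(v) for k, v in venn.items()},
        "venn_excluded": {k: len(v) for k, v in venn_ex.items()},
        "loh_segments": [
            (s.chrom, s.gene_count, s.span_bp, s.dominant_haplotype)
            for s in result["segments"]
        ],
        "taxa": None
        if taxa is None
        else taxa["family_retained"][["taxon", "count", "fraction"]].to_dict(
            "records"
        ),
    }
    report = make_report(summary)
    (outdir / "report.md").write_text(report)
    log.info("pipeline done: outputs in %s", outdir)
    summary["report_path"] = str(outdir / "report.md")
    summary["outdir"] = str(outdir)
    return summary


def make_report(summary: dict) -> str:
    """Human-readable markdown summary of a pipeline run."""
    lines = [
        "# fermase run report",
        "",
        f"Preset: **{summary.get('preset', '?')}**  (seed "
        f"{summary.get('seed', '?')}, {summary.get('n_genes', '?')} genes, "
        f"{summary.get('reads_per_library', '?')} reads/library)",
        "",
        "## Expressed genes per library",
    ]
    expressed = summary.get("expressed")
    if expressed:
        for lib, n in expressed.items():
            thr = summary.get("thresholds", {}).get(lib)
            lines.append(
                f"- {lib}: {n} genes at or above the background threshold"
                + (f" (RPKM >= {thr:.3f})" if thr is not None else "")
            )
    else:
        lines.append("- section absent")
    lines += ["", "## Differential expression"]
    des = summary.get("de")
    if des is None:
        lines.append("- section absent")
    elif des["total"] == 0:
        lines.append("- 0 DE genes")
    else:
        lines.append(
            f"- {des['total']} DE genes ({des['up']} up, {des['down']} down)"
        )
    lines += ["", "## Differential allelic expression (condition Venn)"]
    for scope, key in (("all genes", "venn"), ("LOH region excluded", "venn_excluded")):
        v = summary.get(key)
        if v is None:
            lines.append(f"- {scope}: section absent")
        else:
            lines.append(
                f"- {scope}: both={v['both']}, A_only={v['A_only']}, "
                f"B_only={v['B_only']}"
            )
    lines += ["", "## LOH segments"]
    segs = summary.get("loh_segments")
    if not segs:
        lines.append("- none detected")
    else:
        for chrom, n, span, dom in segs:
            lines.append(
                f"- {chrom}: {n} genes, {span} bp, dominant haplotype {dom}"
            )
    lines += ["", "## Bacterial families (cutoff applied)"]
    taxa = summary.get("taxa")
    if taxa is None:
        lines.append("- section absent")
    else:
        for row in taxa:
            frac = row["fraction"]
            frac_s = "n/a" if frac is None or np.isnan(frac) else f"{frac:.1%}"
            lines.append(f"- {row['taxon']}: {row['count']} reads ({frac_s})")
    lines.append("")
    return "\n".join(lines)
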