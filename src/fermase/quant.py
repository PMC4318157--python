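"""Read counting, RPKM, and the intergenic-background expression filter.

Expression is summarised as RPKM (reads per kilobase of gene model per
million aligned reads), :math:`10^9 C / (N L)` for a gene with :math:`C`
aligned reads and length :math:`L` bp in a library with :math:`N` reads
aligned to genes.  Genomic background transcription is estimated from read
coverage over intergenic regions (>500 bp); a gene whose RPKM falls below
the background threshold in a library is not considered expressed there and
is dropped from differential-expression comparisons when unexpressed in the
libraries being compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fermase.align import STATUS_ALIGNED, AlignmentResult


@dataclass
class LibraryCounts:
    """Exact per-feature read tallies for one library."""

    library_id: str
    gene_counts: pd.Series  # indexed by gene_id, zeros included
    intergenic_counts: pd.Series  # indexed by region_id
    n_aligned_genes: int  # N of the RPKM formula
    n_repeat: int = 0
    n_unaligned: int = 0


@dataclass
class BackgroundThreshold:
    library_id: str
    threshold: float
    quantile: float


def count_per_gene(
    aln: AlignmentResult,
    gene_ids,
    intergenic_ids=(),
    library_id: str = "lib",
) -> LibraryCounts:
    """Tally uniquely aligned reads per gene (and per intergenic region).

    ``N`` is the number of reads aligned to genes, following the study's
    usage of the RPKM denominator; repeats and unaligned reads are carried
    as separate totals so read conservation can be checked.
    """
    gene_ids = list(gene_ids)
    intergenic_ids = list(intergenic_ids)
    mask = aln.status == STATUS_ALIGNED
    feats = aln.feature[mask]
    tallies = np.bincount(feats, minlength=len(aln.names)) if feats.size else (
        np.zeros(len(aln.names), dtype=int)
    )
    by_name = pd.Series(tallies, index=aln.names)
    gene_counts = by_name.reindex(gene_ids, fill_value=0).astype(int)
    ig_counts = by_name.reindex(intergenic_ids, fill_value=0).astype(int)
    return LibraryCounts(
        library_id=library_id,
        gene_counts=gene_counts,
        intergenic_counts=ig_counts,
        n_aligned_genes=int(gene_counts.sum()),
        n_repeat=aln.n_repeat,
        n_unaligned=aln.n_unaligned,
    )


def rpkm(counts, lengths_bp, n_aligned: int):
    """RPKM = 1e9 * C / (N * L); scalar or vectorised over aligned inputs."""
    if n_aligned <= 0:
        raise ValueError("total aligned reads N must be positive")
    c = np.asarray(counts, dtype=float)
    length = np.asarray(lengths_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    out = 1e9 * c / (float(n_aligned) * length)
    if np.ndim(counts) == 0:
        return float(out)
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out


def estimate_background_threshold(
    intergenic_rpkm, quantile: float = 0.95, library_id: str = "lib"
) -> BackgroundThreshold:
    """Nearest-rank empirical quantile of the intergenic RPKM distribution.

    This makes the study's "visual inspection" of the gene/intergenic RPKM
    distributions reproducible: the threshold is the smallest intergenic
    RPKM value whose rank is at least ``quantile`` of the sample.
    """
    values = np.sort(np.asarray(intergenic_rpkm, dtype=float))
    if values.size == 0:
        raise ValueError("no intergenic RPKM values")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    rank = max(1, math.ceil(quantile * values.size))
    return BackgroundThreshold(
        library_id=library_id,
        threshold=float(values[rank - 1]),
        quantile=quantile,
    )


def filter_expressed(rpkm_table: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Per gene x library: True iff RPKM >= that library's threshold."""
    flags = {}
    for lib in rpkm_table.columns:
        if lib not in thresholds:
            raise KeyError(f"no background threshold for library {lib!r}")
        thr = thresholds[lib]
        thr = thr.threshold if isinstance(thr, BackgroundThreshold) else float(thr)
        flags[lib] = rpkm_table[lib] >= thr
    return pd.DataFrame(flags, index=rpkm_table.index)


def ddct_fold_change(
    ct_target_test: float,
    ct_endogenous_test: float,
    ct_target_control: float,
    ct_endogenous_control: float,
) -> float:
    """Relative expression ratio by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_endogenous)_test - (Ct_target - Ct_endogenous)_control.
    """
    for v in (
        ct_target_test,
        ct_endogenous_test,
        ct_target_control,
        ct_endogenous_control,
    ):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_endogenous_test) - (
        ct_target_control - ct_endogenous_control
    )
    return 2.0 ** (-ddct)
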