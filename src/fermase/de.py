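"""Differential expression with the study's calling criteria.

A gene is differentially expressed when its expression ratio is at least
2-fold in either direction *and* the test p-value is below 0.01.  The study
fixed only these thresholds, not the statistic, so the statistic is
specified here explicitly:

* two-library comparisons use the exact conditional binomial construction
  for a rate ratio: given ``C1 + C2`` reads for a gene, ``C1`` is binomial
  with success probability ``N1 / (N1 + N2)`` under the null of equal
  relative expression; the two-sided p-value uses the minimum-likelihood
  rule (scipy's exact binomial test);
* grouped comparisons (time points within a condition treated as
  replicates) use Welch's unequal-variance t-test on log2(RPKM + 1).

No multiple-testing correction is applied by default, matching the raw
``p < 0.01`` cutoff; Benjamini-Hochberg adjustment is available behind a
flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _fold_change(c1, n1, c2, n2):
    """Ratio of normalised counts (library 2 over 1), pseudocount 1 on zeros."""
    a = np.where(c1 == 0, 1.0, c1) / n1
    b = np.where(c2 == 0, 1.0, c2) / n2
    return b / a


def _calls(log2fc, pvalues, alpha, min_ratio):
    lim = np.log2(min_ratio)
    call = np.where(
        (pvalues < alpha) & (log2fc >= lim),
        "up",
        np.where((pvalues < alpha) & (log2fc <= -lim), "down", "none"),
    )
    return call


def de_two_library(
    counts1,
    n1: int,
    counts2,
    n2: int,
    alpha: float = 0.01,
    min_ratio: float = 2.0,
    expressed1=None,
    expressed2=None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call DE genes between two libraries from raw counts.

    ``counts1``/``counts2`` are pandas Series (or arrays) of per-gene read
    counts with ``n1``/``n2`` total gene-aligned reads.  A gene below the
    background threshold in *both* libraries (``expressed1``/``expressed2``
    flags, when given) is excluded from calling.  Returns a DataFrame with
    gene_id, log2fc (library 2 over 1), pvalue, call and excluded flag.
    """
    c1 = np.asarray(counts1, dtype=int)
    c2 = np.asarray(counts2, dtype=int)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("negative counts")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    index = (
        counts1.index
        if isinstance(counts1, pd.Series)
        else pd.RangeIndex(len(c1))
    )
    p_null = n1 / (n1 + n2)
    pvals = np.ones(len(c1))
    for i in range(len(c1)):
        n = int(c1[i] + c2[i])
        if n > 0:
            pvals[i] = stats.binomtest(int(c1[i]), n, p_null).pvalue
    if bh_correct:
        pvals = _benjamini_hochberg(pvals)
    log2fc = np.log2(_fold_change(c1, n1, c2, n2))
    call = _calls(log2fc, pvals, alpha, min_ratio)
    excluded = np.zeros(len(c1), dtype=bool)
    if expressed1 is not None and expressed2 is not None:
        excluded = ~(np.asarray(expressed1) | np.asarray(expressed2))
        call = np.where(excluded, "none", call)
    return pd.DataFrame(
        {
            "gene_id": index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "call": call,
            "excluded_by_threshold": excluded,
        }
    ).set_index("gene_id")


def de_grouped(
    rpkm_table: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.01,
    min_ratio: float = 2.0,
    expressed: pd.DataFrame | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call DE genes between two groups of libraries (>= 2 each).

    Fold change is the ratio of group mean RPKM (B over A, a zero mean
    replaced by 1); the p-value is Welch's t on log2(RPKM + 1).  Genes
    unexpressed in every library of both groups are flagged
    ``excluded_by_threshold`` and not called.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two libraries")
    if set(group_a) & set(group_b):
        raise ValueError("groups must not overlap")
    a = rpkm_table[group_a].to_numpy(dtype=float)
    b = rpkm_table[group_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ratio = np.where(mean_b == 0, 1.0, mean_b) / np.where(mean_a == 0, 1.0, mean_a)
    log2fc = np.log2(ratio)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(
            np.log2(b + 1.0), np.log2(a + 1.0), axis=1, equal_var=False
        )
    pvals = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    if bh_correct:
        pvals = _benjamini_hochberg(pvals)
    call = _calls(log2fc, pvals, alpha, min_ratio)
    excluded = np.zeros(len(rpkm_table), dtype=bool)
    if expressed is not None:
        excluded = ~expressed[group_a + group_b].any(axis=1).to_numpy()
        call = np.where(excluded, "none", call)
    return pd.DataFrame(
        {
            "gene_id": rpkm_table.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "call": call,
            "excluded_by_threshold": excluded,
        }
    ).set_index("gene_id")


def tabulate_de(results: pd.DataFrame) -> dict:
    """Summarise a DE table into total / up / down counts.

    ``down`` means higher in the first (reference) library or group,
    following the table convention of the study.
    """
    up = int((results["call"] == "up").sum())
    down = int((results["call"] == "down").sum())
    return {"total": up + down, "up": up, "down": down}


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
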