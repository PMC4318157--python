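"""Shared fixtures and independent reference implementations (oracles).

The expensive preset workflows are session-scoped so the parameter-recovery
tests and the acceptance checks share one run.
"""

from __future__ import annotations

import pytest

from fermase import pipeline, sim


@pytest.fixture(scope="session")
def smoke_config():
    return sim.preset("smoke")


@pytest.fixture(scope="session")
def smoke_bundle(smoke_config):
    return sim.build_reference(smoke_config)


@pytest.fixture(scope="session")
def smoke_library(smoke_config, smoke_bundle):
    reads, truth = sim.simulate_library(
        smoke_bundle, smoke_config, smoke_config.conditions[0]
    )
    return reads, truth


@pytest.fixture(scope="session")
def fig5_result():
    """Full two-condition DAE/LOH workflow on the planted-architecture preset."""
    return pipeline.run_allelic_workflow(sim.preset("paper_fig5"))


@pytest.fixture(scope="session")
def fig1b_results():
    return {
        name: pipeline.run_taxonomy_workflow(sim.preset(name))
        for name in ("paper_fig1b_fl", "paper_fig1b_tf")
    }


# ---------------------------------------------------------------------------
# oracles


def brute_force_align(read_seq, features, max_mismatches=2):
    """Exhaustive scan over every offset of every feature.

    Returns (status, feature_index, offset, mismatches) with the same
    unique-best / repeat-discard contract as the k-mer matcher.
    """
    best = max_mismatches + 1
    hits = []
    for fi, seq in enumerate(features):
        for st in range(len(seq) - len(read_seq) + 1):
            mm = sum(a != b for a, b in zip(read_seq, seq[st : st + len(read_seq)]))
            if mm < best:
                best = mm
                hits = [(fi, st)]
            elif mm == best:
                hits.append((fi, st))
    if best > max_mismatches or not hits:
        return ("unaligned", -1, -1, -1)
    if len(hits) > 1:
        return ("repeat", -1, -1, best)
    return ("aligned", hits[0][0], hits[0][1], best)


def exact_binomial_pvalue(k, n, p_num, p_den):
    """Two-sided minimum-likelihood exact binomial p-value, in rationals.

    ``p = p_num / p_den``.  Sums the probabilities of all outcomes no more
    likely than the observed one; exact Fraction arithmetic, so the result
    is an independent check on any floating-point implementation.
    """
    from fractions import Fraction
    from math import comb

    p = Fraction(p_num, p_den)
    q = 1 - p
    pmf = [comb(n, j) * p**j * q ** (n - j) for j in range(n + 1)]
    observed = pmf[k]
    return float(sum(x for x in pmf if x <= observed))


def brute_force_loh(statuses, min_genes=10, max_gap=2):
    """All maximal LOH windows by exhaustive enumeration.

    ``statuses`` is a string per gene: '1'/'2' monoallelic with that
    dominant haplotype, 'u' uninformative, 'h' heterozygous-balanced.
    Returns (first, last, mono_count, dominant) tuples.
    """
    n = len(statuses)

    def valid(i, j):
        if statuses[i] not in "12" or statuses[j] != statuses[i]:
            return False
        dom = statuses[i]
        run_gap = 0
        count = 0
        for k in range(i, j + 1):
            s = statuses[k]
            if s == dom:
                count += 1
                run_gap = 0
            elif s == "u":
                run_gap += 1
                if run_gap > max_gap:
                    return False
            else:
                return False
        return count >= min_genes

    out = []
    for i in range(n):
        for j in range(i, n):
            if not valid(i, j):
                continue
            # maximal: no valid window strictly containing this one
            if any(valid(i2, j) for i2 in range(i)) or any(
                valid(i, j2) for j2 in range(j + 1, n)
            ):
                continue
            out.append(
                (i, j, sum(1 for k in range(i, j + 1) if statuses[k] == statuses[i]),
                 int(statuses[i]))
            )
    return out
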