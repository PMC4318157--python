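"""Small shared numerics: exact integer allocation and seeding helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def largest_remainder(total: int, weights) -> np.ndarray:
    """Split ``total`` into integer shares proportional to ``weights``.

    Uses the largest-remainder (Hamilton) rule: floor the exact quotas, then
    hand the leftover units to the largest fractional remainders (ties broken
    by position, which keeps the result deterministic).  Shares always sum to
    ``total`` exactly; a weight of zero receives zero.
    """
    w = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-d sequence")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s == 0:
        if total == 0:
            return np.zeros(w.size, dtype=int)
        raise ValueError("cannot allocate a positive total over zero weights")
    quota = total * (w / s)
    base = np.floor(quota).astype(int)
    leftover = int(total - base.sum())
    if leftover:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:leftover]] += 1
    return base


def split_two(total: int, fraction: float) -> tuple[int, int]:
    """Round ``total * fraction`` to the nearest integer; return (part, rest)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    a = int(np.floor(total * fraction + 0.5))
    return a, total - a


def condition_seed(seed: int, condition: str) -> list[int]:
    """Derive a reproducible RNG seed list from a base seed and a label.

    The label is hashed (sha256) so conditions get independent but stable
    streams regardless of the order in which libraries are simulated.
    """
    h = int.from_bytes(hashlib.sha256(condition.encode()).digest()[:4], "big")
    return [int(seed) % (2**31), h % (2**31)]
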