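"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or exact
arithmetic, independently of the library's algorithms.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from ciliomap.rflp import IUPAC


def locus_state(column: np.ndarray, policy: str) -> str:
    """Per-locus shared state across animals: 'good', 'miss' or 'bad'."""
    col = np.asarray(column)
    if np.any(col == 1):
        return "bad"
    if np.any(col == -1):
        return "miss" if policy == "neutral" else "bad"
    return "good"


def interval_valid(states: list[str], i: int, j: int, max_miss: int) -> bool:
    sub = states[i:j + 1]
    if sub[0] != "good" or sub[-1] != "good":
        return False
    if any(s == "bad" for s in sub):
        return False
    run = 0
    for s in sub:
        run = run + 1 if s == "miss" else 0
        if run > max_miss:
            return False
    return True


def brute_force_shared_regions(
    geno: np.ndarray, min_snps: int, policy: str, max_miss: int
) -> list[tuple[int, int]]:
    """All maximal valid intervals of a (animals x loci) genotype block."""
    n = geno.shape[1]
    states = [locus_state(geno[:, k], policy) for k in range(n)]
    valid = [
        (i, j)
        for i in range(n)
        for j in range(i + min_snps - 1, n)
        if interval_valid(states, i, j, max_miss)
    ]
    maximal = [
        (i, j) for (i, j) in valid
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in valid)
    ]
    return sorted(maximal)


def brute_force_runs(
    codes: np.ndarray, min_snps: int, policy: str, max_miss: int
) -> list[tuple[int, int]]:
    """Single-animal homozygosity runs via the same interval enumeration."""
    return brute_force_shared_regions(
        codes.reshape(1, -1), min_snps, policy, max_miss)


def fisher_exact_fraction(table) -> Fraction:
    """Two-tailed Fisher exact p in exact rational arithmetic.

    Sums hypergeometric probabilities of every margin-consistent table no
    more likely than the observed one (exact <= comparison).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return total


def brute_force_sites(sequence: str, pattern: str) -> list[int]:
    """Pattern positions by expanding the IUPAC pattern into its full set
    of concrete words and testing every offset for membership."""
    from itertools import product

    words = {"".join(w) for w in product(*(IUPAC[p] for p in pattern))}
    seq = sequence.upper()
    m = len(pattern)
    return [i for i in range(len(seq) - m + 1) if seq[i:i + m] in words]
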