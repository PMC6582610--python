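"""Exhaustive solver for small DDP instances.

Enumerates every chromosome in S_m x S_n in lexicographic order and scores
it exactly.  Used as the ground-truth oracle in tests and for diagnosing how
sparse an instance's solution set is.  A size guard refuses searches beyond
``limit`` chromosomes; the oracle's job is certainty, not speed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import permutations

from . import core
from .core import DDPInstance, DigestMapError

__all__ = ["OracleResult", "solve_exhaustive", "min_mismatch_landscape"]


@dataclass
class OracleResult:
    solutions: list  # (mu, nu) pairs with mismatch 0, lexicographic order
    min_mismatch: int
    searched: int  # m! * n!
    canonical_count: int  # solutions up to the mirror (reverse-reading) map

    @property
    def solvable(self) -> bool:
        return self.min_mismatch == 0


def _prepare(inst: DDPInstance, limit: int):
    core._require_valid(inst)
    padded = core.pad_to_canonical(inst)
    size = math.factorial(padded.m) * math.factorial(padded.n)
    if size > limit:
        raise DigestMapError(f"search space m!*n! = {size} exceeds limit {limit}")
    return padded, size


def _iter_scores(padded: DDPInstance):
    a, b, c = padded.a, padded.b, padded.c
    m, n = len(a), len(b)
    c_sorted = sorted(c)
    k = len(c)
    b_orders = list(permutations(range(1, n + 1)))
    # precompute interior cut positions for each nu
    b_cuts = []
    for nu in b_orders:
        s = 0
        cuts = []
        for j in nu[:-1]:
            s += b[j - 1]
            cuts.append(s)
        b_cuts.append(cuts)
    L = sum(a)
    for mu in permutations(range(1, m + 1)):
        s = 0
        a_pos = []
        for i in mu:
            s += a[i - 1]
            a_pos.append(s)
        for nu, cuts in zip(b_orders, b_cuts):
            pos = sorted(a_pos + cuts)
            prev = 0
            frags = []
            for p in pos:
                frags.append(p - prev)
                prev = p
            frags.sort()
            i = j = common = 0
            while i < k and j < k:
                if frags[i] == c_sorted[j]:
                    common += 1
                    i += 1
                    j += 1
                elif frags[i] < c_sorted[j]:
                    i += 1
                else:
                    j += 1
            yield mu, nu, 2 * (k - common)


def solve_exhaustive(inst: DDPInstance, limit: int = 10_000_000) -> OracleResult:
    """All exact solutions and the global minimum mismatch, by enumeration."""
    padded, size = _prepare(inst, limit)
    solutions = []
    best = None
    for mu, nu, mis in _iter_scores(padded):
        if best is None or mis < best:
            best = mis
        if mis == 0:
            solutions.append((mu, nu))
    orbits = {frozenset({sol, (core.mirror(sol[0]), core.mirror(sol[1]))}) for sol in solutions}
    return OracleResult(
        solutions=solutions,
        min_mismatch=best,
        searched=size,
        canonical_count=len(orbits),
    )


def min_mismatch_landscape(inst: DDPInstance, limit: int = 10_000_000) -> Counter:
    """Histogram of mismatch values over the whole search space."""
    padded, _ = _prepare(inst, limit)
    hist = Counter()
    for _, _, mis in _iter_scores(padded):
        hist[mis] += 1
    return hist
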