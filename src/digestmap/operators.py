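"""Genetic operators over permutation-pair chromosomes.

Six operators drive the search over S_m x S_n:

* RWS — roulette-wheel (fitness-proportional) selection;
* PCC — permutation-composition crossover;
* RSC — referenced-sorting crossover (order-preserving): the suffix after a
  cut point is rearranged into the order its elements appear in the
  co-parent;
* P4X — double transposition: one swap in mu and one in nu;
* FLP — reversal of a contiguous segment;
* CSH — cyclic left shift of a contiguous segment.

The mutation probability follows a sawtooth schedule: within each cycle of
``cycle_length`` generations it rises linearly from ``2 / (m + n)`` to
``ceiling``.  The ceiling defaults to 0.55 so that the increment stays
non-negative even for the smallest instances (m = n = 2 starts at 0.5).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Chromosome, DigestMapError, SizeMismatchError, compose

__all__ = [
    "CROSSOVER_NAMES",
    "MUTATION_NAMES",
    "OperatorSet",
    "MutationSchedule",
    "mutation_probability",
    "rws_select",
    "refer_sort",
    "pcc_cross",
    "rsc_cross",
    "rsc_cross_sequences",
    "flip_segment",
    "cyclic_shift_segment",
    "p4x_mutate",
    "flp_mutate",
    "csh_mutate",
]

CROSSOVER_NAMES = ("pcc", "rsc")
MUTATION_NAMES = ("p4x", "flp", "csh")


@dataclass(frozen=True)
class OperatorSet:
    """Which crossovers and mutations a GA run may apply (selection is RWS)."""

    crossovers: tuple = CROSSOVER_NAMES
    mutations: tuple = MUTATION_NAMES

    def __post_init__(self):
        for x in self.crossovers:
            if x not in CROSSOVER_NAMES:
                raise DigestMapError(f"unknown crossover operator {x!r}")
        for x in self.mutations:
            if x not in MUTATION_NAMES:
                raise DigestMapError(f"unknown mutation operator {x!r}")

    @property
    def runnable(self) -> bool:
        """At least one variation operator is enabled."""
        return bool(self.crossovers or self.mutations)

    @classmethod
    def from_names(cls, names) -> "OperatorSet":
        """Parse names like ``"all"``, ``"rws,pcc"`` or ``["rsc", "flp"]``.

        ``rws`` is accepted and ignored (selection is always enabled);
        ``all`` enables both crossovers and all three mutations.
        """
        if isinstance(names, str):
            names = names.split(",")
        toks = [str(t).strip().lower() for t in names if str(t).strip()]
        if "all" in toks:
            return cls()
        cx = tuple(t for t in CROSSOVER_NAMES if t in toks)
        mu = tuple(t for t in MUTATION_NAMES if t in toks)
        unknown = [t for t in toks if t not in CROSSOVER_NAMES + MUTATION_NAMES + ("rws",)]
        if unknown:
            raise DigestMapError(f"unknown operator name(s): {unknown}")
        if not (cx or mu):
            raise DigestMapError("operator set needs at least one crossover or mutation")
        return cls(crossovers=cx, mutations=mu)

    def label(self) -> str:
        if self.crossovers == CROSSOVER_NAMES and self.mutations == MUTATION_NAMES:
            return "all"
        return ",".join(self.crossovers + self.mutations)


#: The benchmark configurations: every crossover x mutation pair (the six
#: combinations of the variation operators) plus the everything-enabled set.
BENCHMARK_OPERATOR_SETS = tuple(
    OperatorSet(crossovers=(c,), mutations=(m,))
    for c in CROSSOVER_NAMES
    for m in MUTATION_NAMES
) + (OperatorSet(),)

__all__.append("BENCHMARK_OPERATOR_SETS")


@dataclass(frozen=True)
class MutationSchedule:
    """Cyclic linear ramp of the per-offspring mutation probability."""

    cycle_length: int = 200
    ceiling: float = 0.55

    def floor(self, m: int, n: int) -> float:
        return 2.0 / (m + n)


def mutation_probability(
    generation: int, m: int, n: int, sched: MutationSchedule = MutationSchedule()
) -> float:
    """Mutation probability at ``generation`` (0-based within the run).

    ``p(g) = floor + (ceiling - floor) * (g mod cycle) / (cycle - 1)`` with
    ``floor = 2 / (m + n)``; rises from the floor at each cycle start to the
    ceiling at the cycle end.  For degenerate degrees (m + n < 4) the floor
    would exceed the ceiling, so it is clamped to the ceiling: the increment
    is non-negative for every m + n >= 2.
    """
    if m + n < 2:
        raise DigestMapError("mutation_probability requires m + n >= 2")
    hi = sched.ceiling
    lo = min(sched.floor(m, n), hi)
    phase = (generation % sched.cycle_length) / (sched.cycle_length - 1)
    return lo + (hi - lo) * phase


# ---------------------------------------------------------------------------
# selection


def rws_select(fitnesses: Sequence[float], count: int, rng: np.random.Generator) -> np.ndarray:
    """Roulette-wheel selection: ``count`` indices drawn with replacement,
    probability proportional to fitness."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise DigestMapError("rws_select on an empty population")
    if np.any(f <= 0):
        raise DigestMapError("rws_select requires strictly positive fitnesses")
    if count < 1:
        raise DigestMapError("rws_select count must be >= 1")
    return rng.choice(f.size, size=count, p=f / f.sum())


# ---------------------------------------------------------------------------
# crossover


def pcc_cross(ch1: Chromosome, ch2: Chromosome) -> tuple:
    """Permutation-composition crossover.

    Offspring are ``(mu1 o mu2, nu1 o nu2)`` and ``(mu2 o mu1, nu2 o nu1)``
    with ``(p o q)(i) = p(q(i))``.
    """
    o1 = Chromosome(compose(ch1.mu, ch2.mu), compose(ch1.nu, ch2.nu))
    o2 = Chromosome(compose(ch2.mu, ch1.mu), compose(ch2.nu, ch1.nu))
    return o1, o2


def refer_sort(target: Sequence, reference: Sequence) -> tuple:
    """Rearrange ``target`` into the order its elements occupy in ``reference``.

    The result is the rightmost subsequence of ``reference`` realizing
    ``target``'s multiset (greedy right-to-left occurrence matching), which
    reproduces the referenced-sorting chains used by the order-preserving
    crossover.  Raises if ``reference`` lacks the needed multiplicities.
    """
    need = Counter(target)
    taken = []
    for x in reversed(tuple(reference)):
        if need.get(x, 0) > 0:
            need[x] -= 1
            taken.append(x)
    missing = {k: v for k, v in need.items() if v > 0}
    if missing:
        raise DigestMapError(f"refer_sort: reference lacks occurrences of {missing}")
    return tuple(reversed(taken))


def rsc_cross_sequences(p1: Sequence, p2: Sequence, point: int) -> tuple:
    """Value-level referenced-sorting crossover at a given cut ``point``.

    Offspring keep the parent's prefix and replace the suffix with its
    referenced sort against the *whole* co-parent.
    """
    if not 1 <= point < min(len(p1), len(p2)):
        raise DigestMapError(f"crossover point {point} out of range")
    c1 = tuple(p1[:point]) + refer_sort(p1[point:], p2)
    c2 = tuple(p2[:point]) + refer_sort(p2[point:], p1)
    return c1, c2


def rsc_cross(ch1: Chromosome, ch2: Chromosome, rng: np.random.Generator) -> tuple:
    """Referenced-sorting crossover on a chromosome pair.

    For mu and nu independently, a cut point is drawn uniformly on
    ``1..degree-1`` (shared by the two offspring of that component).  On
    permutations the referenced sort is exact, so offspring are bijections.
    """
    m, n = len(ch1.mu), len(ch1.nu)
    if len(ch2.mu) != m or len(ch2.nu) != n:
        raise SizeMismatchError("rsc_cross parents have mismatched degrees")
    if m < 2 or n < 2:
        raise DigestMapError("rsc_cross requires degree >= 2")
    tm = int(rng.integers(1, m))
    tn = int(rng.integers(1, n))
    mu1, mu2 = rsc_cross_sequences(ch1.mu, ch2.mu, tm)
    nu1, nu2 = rsc_cross_sequences(ch1.nu, ch2.nu, tn)
    return Chromosome(mu1, nu1), Chromosome(mu2, nu2)


# ---------------------------------------------------------------------------
# mutation


def _segment(degree: int, rng: np.random.Generator) -> tuple:
    """Uniform contiguous segment [i, j], 0-based inclusive, i < j."""
    pairs = degree * (degree - 1) // 2
    r = int(rng.integers(pairs))
    # unrank the r-th pair (i, j) with i < j in lexicographic order
    i = 0
    while r >= degree - 1 - i:
        r -= degree - 1 - i
        i += 1
    return i, i + 1 + r

def flip_segment(seq: Sequence, i: int, j: int) -> tuple:
    """Reverse the segment seq[i..j] (0-based, inclusive)."""
    s = tuple(seq)
    return s[:i] + s[i : j + 1][::-1] + s[j + 1 :]


def cyclic_shift_segment(seq: Sequence, i: int, j: int) -> tuple:
    """Rotate the segment seq[i..j] left by one position."""
    s = tuple(seq)
    return s[:i] + s[i + 1 : j + 1] + (s[i],) + s[j + 1 :]


def flp_mutate(p: Sequence[int], rng: np.random.Generator) -> tuple:
    """Reverse a uniformly drawn contiguous segment of the permutation."""
    if len(p) < 2:
        raise DigestMapError("flp_mutate requires degree >= 2")
    i, j = _segment(len(p), rng)
    return flip_segment(p, i, j)


def csh_mutate(p: Sequence[int], rng: np.random.Generator) -> tuple:
    """Cyclically left-shift a uniformly drawn contiguous segment."""
    if len(p) < 2:
        raise DigestMapError("csh_mutate requires degree >= 2")
    i, j = _segment(len(p), rng)
    return cyclic_shift_segment(p, i, j)


def p4x_mutate(ch: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Apply one transposition to mu and one to nu (four loci touched).

    Positions are drawn without replacement, so the result always differs
    from the input.
    """
    if len(ch.mu) < 2 or len(ch.nu) < 2:
        raise DigestMapError("p4x_mutate requires m >= 2 and n >= 2")

    def swap(p):
        i, j = rng.choice(len(p), size=2, replace=False)
        q = list(p)
        q[i], q[j] = q[j], q[i]
        return tuple(q)

    return Chromosome(swap(ch.mu), swap(ch.nu))
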