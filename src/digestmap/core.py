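"""Vector arithmetic for double digest restriction maps.

A double digest experiment cuts a DNA molecule with restriction enzyme A
alone, enzyme B alone, and both together, yielding three multisets of
fragment lengths ``a`` (m entries), ``b`` (n entries) and ``c`` (k entries).
The double digest problem (DDP) asks for orderings of the A- and B-fragments
whose overlaid cut sites reproduce ``c``.  This module provides the vector
formulation of that problem:

* fragment vectors are tuples of non-negative integer lengths; prefix sums
  (``accumulative_sum``) are cut positions, and ``step_difference`` is the
  inverse operation;
* an ordering is a permutation acting on a fragment vector by *gather*:
  ``permute(v, p)[i] = v[p(i)]`` with 1-based one-line notation;
* ``dds(a, b)`` is the double digest sequence implied by ordered ``a`` and
  ``b``: merge both enzymes' cut positions, sort, and take step differences.
  Zero entries mark coincident cut sites;
* a candidate solution is a permutation pair ``(mu, nu)`` scored by the
  multiset mismatch between ``dds(a^mu, b^nu)`` and ``c``, giving the GA
  fitness ``1 / (1 + mismatch)``; mismatch 0 means an exact map.

All functions are pure and operate on plain tuples so that results are
hashable and trivially serializable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "DigestMapError",
    "SizeMismatchError",
    "InvalidInstanceError",
    "Fragments",
    "Permutation",
    "accumulative_sum",
    "step_difference",
    "identity_permutation",
    "inverse",
    "compose",
    "mirror",
    "is_permutation",
    "permute",
    "combine",
    "dds",
    "multiset_mismatch",
    "DDPInstance",
    "ValidityReport",
    "validate",
    "pad_to_canonical",
    "mismatch_of",
    "fitness_of",
    "Chromosome",
    "SolutionRecord",
    "extract_pi",
    "solution_record",
    "map_distance",
]

Fragments = tuple  # tuple[int, ...] — fragment lengths in base pairs
Permutation = tuple  # tuple[int, ...] — 1-based one-line notation


class DigestMapError(ValueError):
    """Base class for all domain errors raised by this package."""


class SizeMismatchError(DigestMapError):
    """Operands have incompatible lengths or degrees."""


class InvalidInstanceError(DigestMapError):
    """A DDP instance violates the equal-total-length restriction."""


def _as_int_tuple(v: Iterable, what: str = "vector") -> tuple:
    out = tuple(int(x) for x in v)
    for x in out:
        if x < 0:
            raise DigestMapError(f"{what} entries must be >= 0, got {x}")
    return out


# ---------------------------------------------------------------------------
# prefix sums and their inverse


def accumulative_sum(v: Sequence[int]) -> tuple:
    """Prefix-sum vector of ``v``; entry j is the cut position after fragment j."""
    if len(v) == 0:
        raise DigestMapError("accumulative_sum of an empty vector")
    out = []
    s = 0
    for x in v:
        s += x
        out.append(s)
    return tuple(out)


def step_difference(v: Sequence[int]) -> Fragments:
    """Consecutive differences of a non-decreasing position vector.

    Inverse of :func:`accumulative_sum`.  A zero difference corresponds to a
    repeated cut position, i.e. a coincident cut site.
    """
    if len(v) == 0:
        raise DigestMapError("step_difference of an empty vector")
    out = [v[0]]
    for prev, cur in zip(v, v[1:]):
        if cur < prev:
            raise DigestMapError(f"step_difference input must be non-decreasing ({prev} > {cur})")
        out.append(cur - prev)
    if v[0] < 0:
        raise DigestMapError("step_difference input must be non-negative")
    return tuple(out)


# ---------------------------------------------------------------------------
# permutations (1-based one-line notation)


def is_permutation(p: Sequence[int]) -> bool:
    return sorted(p) == list(range(1, len(p) + 1))


def _check_permutation(p: Sequence[int]) -> tuple:
    p = tuple(int(x) for x in p)
    if not is_permutation(p):
        raise DigestMapError(f"not a permutation of 1..{len(p)}: {p}")
    return p


def identity_permutation(n: int) -> Permutation:
    return tuple(range(1, n + 1))


def inverse(p: Sequence[int]) -> Permutation:
    p = _check_permutation(p)
    out = [0] * len(p)
    for i, x in enumerate(p, start=1):
        out[x - 1] = i
    return tuple(out)


def compose(p: Sequence[int], q: Sequence[int]) -> Permutation:
    """Composition ``(p o q)(i) = p(q(i))``."""
    if len(p) != len(q):
        raise SizeMismatchError(f"cannot compose degrees {len(p)} and {len(q)}")
    return tuple(p[x - 1] for x in q)


def mirror(p: Sequence[int]) -> Permutation:
    """The permutation realizing the reversed arrangement: ``p'(i) = p(deg+1-i)``.

    If ``permute(v, p)`` is an ordering of ``v`` then ``permute(v, mirror(p))``
    is that ordering read right to left — reading a physical map from the
    other end of the molecule.
    """
    return tuple(reversed(tuple(p)))


def permute(v: Sequence, p: Sequence[int]):
    """Gather action of a permutation on a vector: ``result[i] = v[p(i)]``."""
    p = _check_permutation(p)
    if len(v) != len(p):
        raise SizeMismatchError(f"vector length {len(v)} != permutation degree {len(p)}")
    return tuple(v[x - 1] for x in p)


# ---------------------------------------------------------------------------
# double digest sequence


def combine(a: Sequence[int], b: Sequence[int]) -> tuple:
    """Combining sequence: all cut positions of ordered ``a`` plus the interior
    cut positions of ordered ``b`` (the shared total is kept once)."""
    if sum(a) != sum(b):
        raise InvalidInstanceError(f"combine requires equal totals, got {sum(a)} != {sum(b)}")
    return accumulative_sum(a) + accumulative_sum(b)[:-1]


def dds(a: Sequence[int], b: Sequence[int]) -> Fragments:
    """Double digest sequence of ordered ``a`` and ordered ``b``.

    Sort the combined cut positions and take step differences: the fragment
    lengths produced by cutting with both enzymes at once.  Always has
    ``m + n - 1`` entries; zeros appear exactly at coincident cut sites.
    """
    return step_difference(tuple(sorted(combine(a, b))))


def multiset_mismatch(x: Sequence[int], y: Sequence[int]) -> int:
    """Size of the multiset symmetric difference ``|x (+) y|``.

    ``|x| + |y| - 2|x n y|`` with multiplicity; 0 iff ``x`` and ``y`` are
    equal as multisets.  Even whenever ``len(x) == len(y)``.
    """
    cx = Counter(x)
    cy = Counter(y)
    common = sum(min(cx[v], cy[v]) for v in cx)
    return len(x) + len(y) - 2 * common


# ---------------------------------------------------------------------------
# instances


@dataclass(frozen=True)
class DDPInstance:
    """A DDP instance: fragment-length vectors of the A, B and double digests."""

    a: Fragments
    b: Fragments
    c: Fragments
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "a", _as_int_tuple(self.a, "a"))
        object.__setattr__(self, "b", _as_int_tuple(self.b, "b"))
        object.__setattr__(self, "c", _as_int_tuple(self.c, "c"))

    @property
    def m(self) -> int:
        return len(self.a)

    @property
    def n(self) -> int:
        return len(self.b)

    @property
    def k(self) -> int:
        return len(self.c)

    @property
    def total_length(self) -> int:
        return sum(self.a)

    @property
    def is_canonical(self) -> bool:
        """True when ``k == m + n - 1`` (no padding needed)."""
        return self.k == self.m + self.n - 1

    @property
    def rho_c(self) -> int:
        """Maximum double-digest fragment length, max c_i."""
        return max(self.c)


@dataclass(frozen=True)
class ValidityReport:
    sum_a: int
    sum_b: int
    sum_c: int
    valid: bool

    def summary(self) -> str:
        verdict = "valid" if self.valid else "INVALID"
        return f"{verdict}: sum(a)={self.sum_a}, sum(b)={self.sum_b}, sum(c)={self.sum_c}"


def validate(inst: DDPInstance) -> ValidityReport:
    """Check the equal-total restriction; reports, never raises."""
    sa, sb, sc = sum(inst.a), sum(inst.b), sum(inst.c)
    return ValidityReport(sa, sb, sc, sa == sb == sc)


def _require_valid(inst: DDPInstance) -> None:
    rep = validate(inst)
    if not rep.valid:
        raise InvalidInstanceError(f"instance {inst.name!r} {rep.summary()}")


def pad_to_canonical(inst: DDPInstance) -> DDPInstance:
    """Zero-pad so that ``k == m + n - 1`` exactly.

    Coincident cut sites make the observed double digest shorter than
    ``m + n - 1``; experimental artefacts can also make it longer.  Padding
    appends length-0 fragments: to ``c`` when k is short, or to the shorter
    of ``a`` and ``b`` (tie: ``a``) when k is long.  Totals are unchanged.
    """
    _require_valid(inst)
    delta = (inst.m + inst.n - 1) - inst.k
    if delta == 0:
        return inst
    if delta > 0:
        return replace(inst, c=inst.c + (0,) * delta)
    # k > m + n - 1: pad the shorter single digest (tie: pad a)
    if inst.m <= inst.n:
        return replace(inst, a=inst.a + (0,) * (-delta))
    return replace(inst, b=inst.b + (0,) * (-delta))


def mismatch_of(mu: Sequence[int], nu: Sequence[int], inst: DDPInstance) -> int:
    """Multiset mismatch between ``dds(a^mu, b^nu)`` and ``c``."""
    if not inst.is_canonical:
        raise DigestMapError("instance must be padded to k = m + n - 1 (use pad_to_canonical)")
    _require_valid(inst)
    return multiset_mismatch(dds(permute(inst.a, mu), permute(inst.b, nu)), inst.c)


def fitness_of(mu: Sequence[int], nu: Sequence[int], inst: DDPInstance) -> float:
    """GA fitness ``1 / (1 + mismatch)``; in (0, 1], and 1 iff exact."""
    return 1.0 / (1.0 + mismatch_of(mu, nu, inst))


# ---------------------------------------------------------------------------
# solutions


@dataclass
class Chromosome:
    """A candidate solution: orderings of the A- and B-fragments."""

    mu: Permutation
    nu: Permutation
    fitness: float | None = None


@dataclass
class SolutionRecord:
    """A scored (mu, nu) pair with its realized double digest sequence.

    ``pi`` is the arrangement of ``c`` matching the realized sequence
    entrywise (only defined for exact solutions, else None).
    """

    mu: Permutation
    nu: Permutation
    pi: Permutation | None
    dds: Fragments
    mismatch: int
    fitness: float
    generation_found: int = 0


def extract_pi(mu: Sequence[int], nu: Sequence[int], inst: DDPInstance) -> Permutation:
    """Arrangement ``pi`` of ``c`` with ``permute(c, pi) == dds(a^mu, b^nu)``.

    Only defined for exact solutions.  Ties among equal fragment lengths are
    broken by ascending original index in ``c`` (stable), so the result is
    deterministic even though ``pi`` is not unique.  Runs in O(k log k).
    """
    if mismatch_of(mu, nu, inst) != 0:
        raise DigestMapError("extract_pi requires an exact solution (mismatch 0)")
    realized = dds(permute(inst.a, mu), permute(inst.b, nu))
    # positions of the realized sequence in (value, position) order are fed
    # c's indices in the same stable (value, index) order
    by_value_pos = sorted(range(len(realized)), key=lambda i: (realized[i], i))
    c_indices = sorted(range(len(inst.c)), key=lambda i: (inst.c[i], i))
    pi = [0] * len(realized)
    for pos, ci in zip(by_value_pos, c_indices):
        pi[pos] = ci + 1
    return tuple(pi)


def solution_record(
    mu: Sequence[int], nu: Sequence[int], inst: DDPInstance, generation_found: int = 0
) -> SolutionRecord:
    """Build a fully scored :class:`SolutionRecord` from scratch."""
    mis = mismatch_of(mu, nu, inst)
    realized = dds(permute(inst.a, mu), permute(inst.b, nu))
    pi = extract_pi(mu, nu, inst) if mis == 0 else None
    return SolutionRecord(
        mu=tuple(mu),
        nu=tuple(nu),
        pi=pi,
        dds=realized,
        mismatch=mis,
        fitness=1.0 / (1.0 + mis),
        generation_found=generation_found,
    )


def map_distance(sol1: SolutionRecord, sol2: SolutionRecord, L: int) -> float:
    """Relative displacement between two maps of the same molecule.

    Interior cut positions (prefix sums of each realized double digest,
    excluding the total length L) are matched in sorted order and their L1
    displacement is normalized by L.  0 iff the cut sets coincide; symmetric.
    """
    if len(sol1.dds) != len(sol2.dds):
        raise SizeMismatchError(
            f"map_distance needs equal k, got {len(sol1.dds)} and {len(sol2.dds)}"
        )
    u = sorted(accumulative_sum(sol1.dds)[:-1])
    w = sorted(accumulative_sum(sol2.dds)[:-1])
    return sum(abs(x - y) for x, y in zip(u, w)) / L
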