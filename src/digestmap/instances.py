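"""Random DDP instances, the scaling-rounding-adjusting transform, fixtures.

The generator builds instances from cut positions, so every emitted instance
is valid (equal totals) and ships with its generating orderings as a
certified ground truth.  Two sampling modes:

* unconstrained: interior cut sites of each enzyme are drawn uniformly
  without replacement from ``1..L-1``; sites shared by both enzymes are
  allowed and produce coincident cuts (the emitted double digest drops the
  resulting zero-length fragments, so ``k < m + n - 1`` until padding);
* capped ``rho_c_max``: the double digest fragment lengths are drawn as a
  uniform random composition of L into ``m + n - 1`` parts in
  ``[1, rho_c_max]`` (exact conditional sampling via a count table), and the
  interior cut sites are then split at random between the two enzymes.

The scaling-rounding-adjusting transform shrinks a numerically hard
instance: multiply all lengths by a scale factor, round, and if the three
totals disagree retry with the rounding nudged by ±t.  Candidates are tried
plain → up → down by default and the first valid one is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import core
from .core import DDPInstance, DigestMapError, SolutionRecord

__all__ = [
    "GeneratorSpec",
    "ScalingReport",
    "random_instance",
    "scale_round_adjust",
    "default_scale_factor",
    "fixtures",
    "EXAMPLE1",
    "INS2_PRIME",
    "SCALED_PLAIN",
    "SCALED_UP",
    "RSC_PARENTS",
    "FLP_EXAMPLE",
    "CSH_EXAMPLE",
]


# ---------------------------------------------------------------------------
# random instances


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one random instance draw."""

    m: int
    n: int
    total_length: int
    rho_c_max: int | None = None  # cap on max double-digest fragment length
    seed: int | None = None

    def check_feasible(self) -> None:
        m, n, L = self.m, self.n, self.total_length
        if m < 1 or n < 1:
            raise DigestMapError("m and n must be >= 1")
        if L < max(m, n):
            raise DigestMapError(f"total length {L} cannot host {max(m, n)} fragments >= 1")
        if self.rho_c_max is not None:
            k = m + n - 1
            if self.rho_c_max < 1 or self.rho_c_max > L:
                raise DigestMapError("rho_c_max must be in 1..total_length")
            if self.rho_c_max * k < L:
                raise DigestMapError(
                    f"infeasible: {k} double-digest fragments of length <= "
                    f"{self.rho_c_max} cannot sum to {L}"
                )


@lru_cache(maxsize=None)
def _composition_counts(parts: int, total: int, hi: int) -> tuple:
    """N[s] = number of compositions of s into `parts` parts in [1, hi]."""
    if parts == 0:
        return tuple(1 if s == 0 else 0 for s in range(total + 1))
    prev = _composition_counts(parts - 1, total, hi)
    out = []
    for s in range(total + 1):
        lo = max(1, s - (parts - 1) * hi)  # part value bounds that keep the rest feasible
        out.append(sum(prev[s - x] for x in range(lo, min(hi, s) + 1)))
    return tuple(out)


def _randbelow(total: int, rng: np.random.Generator) -> int:
    """Uniform integer in [0, total) for arbitrarily large Python ints."""
    nbits = total.bit_length()
    while True:
        r = 0
        for _ in range(0, nbits, 32):
            r = (r << 32) | int(rng.integers(0, 1 << 32))
        r &= (1 << nbits) - 1
        if r < total:
            return r


def _sample_capped_composition(k: int, L: int, hi: int, rng: np.random.Generator) -> list:
    """Uniform composition of L into k parts each in [1, hi] (exact counts)."""
    counts = {j: _composition_counts(j, L, hi) for j in range(k)}
    parts = []
    s = L
    for j in range(k, 0, -1):
        if j == 1:
            parts.append(s)
            break
        total = sum(counts[j - 1][s - x] for x in range(max(1, s - (j - 1) * hi), min(hi, s) + 1))
        r = _randbelow(total, rng)
        acc = 0
        for x in range(max(1, s - (j - 1) * hi), min(hi, s) + 1):
            acc += counts[j - 1][s - x]
            if r < acc:
                parts.append(x)
                s -= x
                break
    return parts


def _shuffled_with_truth(v: tuple, rng: np.random.Generator) -> tuple:
    """Return (shuffled vector, permutation recovering the true order)."""
    sigma = tuple(int(x) + 1 for x in rng.permutation(len(v)))
    shuffled = core.permute(v, sigma)
    # permute(shuffled, inverse(sigma)) == v
    return shuffled, core.inverse(sigma)


def random_instance(spec: GeneratorSpec, rng: np.random.Generator | None = None):
    """Draw a valid instance plus its certified ground-truth solution.

    Returns ``(instance, truth)`` where ``truth`` is a
    :class:`~digestmap.core.SolutionRecord` with fitness 1 on the padded
    instance.  The emitted ``a`` and ``b`` are shuffled; ``c`` is sorted
    ascending, as fragment-length data comes off a gel.
    """
    spec.check_feasible()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m, n, L = spec.m, spec.n, spec.total_length

    if spec.rho_c_max is None:
        a_cuts = sorted(int(x) + 1 for x in rng.choice(L - 1, size=m - 1, replace=False)) if m > 1 else []
        b_cuts = sorted(int(x) + 1 for x in rng.choice(L - 1, size=n - 1, replace=False)) if n > 1 else []
    else:
        k = m + n - 1
        c_parts = _sample_capped_composition(k, L, spec.rho_c_max, rng)
        interior = list(core.accumulative_sum(c_parts)[:-1])
        picks = sorted(int(x) for x in rng.choice(k - 1, size=m - 1, replace=False)) if m > 1 else []
        a_cuts = [interior[i] for i in picks]
        b_cuts = [p for i, p in enumerate(interior) if i not in set(picks)]

    a_true = core.step_difference(tuple(a_cuts) + (L,))
    b_true = core.step_difference(tuple(b_cuts) + (L,))
    c_full = core.dds(a_true, b_true)
    c = tuple(sorted(x for x in c_full if x > 0))  # coincident cuts observed as absent fragments

    a, mu = _shuffled_with_truth(a_true, rng)
    b, nu = _shuffled_with_truth(b_true, rng)
    name = f"random-m{m}-n{n}-L{L}" + ("" if spec.rho_c_max is None else f"-rho{spec.rho_c_max}")
    inst = DDPInstance(a=a, b=b, c=c, name=name)
    truth = core.solution_record(mu, nu, core.pad_to_canonical(inst))
    return inst, truth


# ---------------------------------------------------------------------------
# scaling-rounding-adjusting


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class ScalingReport:
    """Outcome of the scaling-rounding-adjusting transform."""

    factor: float
    t: float
    variant: str | None  # "plain" | "up" | "down" | None if all invalid
    scaled: DDPInstance | None
    candidates: dict  # variant -> DDPInstance
    sums: dict  # variant -> (sum_a, sum_b, sum_c)

    @property
    def failed(self) -> bool:
        return self.variant is None


def default_scale_factor(inst: DDPInstance) -> float:
    """Smallest power of ten keeping the shortest double-digest fragment >= 1."""
    mc = min(x for x in inst.c if x > 0)
    return 10.0 ** -int(math.floor(math.log10(mc)))


def scale_round_adjust(
    inst: DDPInstance,
    factor: float,
    t: float = 0.1,
    order: tuple = ("plain", "up", "down"),
) -> ScalingReport:
    """Shrink an instance by ``factor`` and repair rounding damage.

    Three candidates are formed — ``plain``: round(x*factor), ``up``:
    round(x*factor + t), ``down``: round(x*factor - t) (round = half away
    from zero) — and the first valid one in ``order`` is selected.  All
    three sum-triples are reported for audit.
    """
    core._require_valid(inst)
    if not (0 < factor <= 1):
        raise DigestMapError("factor must be in (0, 1]")
    if not (0.0001 <= t <= 0.4999):
        raise DigestMapError("adjust constant t must be in [0.0001, 0.4999]")
    shifts = {"plain": 0.0, "up": t, "down": -t}
    if set(order) != set(shifts):
        raise DigestMapError(f"order must be a permutation of {tuple(shifts)}")

    def transform(shift):
        def f(v):
            return tuple(max(0, _round_half_up(x * factor + shift)) for x in v)

        return DDPInstance(f(inst.a), f(inst.b), f(inst.c), name=f"{inst.name}-scaled")

    candidates = {v: transform(s) for v, s in shifts.items()}
    sums = {
        v: (sum(ci.a), sum(ci.b), sum(ci.c)) for v, ci in candidates.items()
    }
    variant = next((v for v in order if core.validate(candidates[v]).valid), None)
    return ScalingReport(
        factor=factor,
        t=t,
        variant=variant,
        scaled=candidates[variant] if variant else None,
        candidates=candidates,
        sums=sums,
    )


# ---------------------------------------------------------------------------
# printed fixtures

#: Small worked instance: a length-11 molecule, 4 + 4 fragments.
EXAMPLE1 = DDPInstance(a=(1, 2, 3, 5), b=(2, 2, 3, 4), c=(1, 1, 1, 2, 2, 2, 2), name="example1")

#: The adjusted (rounded-down) surrogate of the hard benchmark instance.
INS2_PRIME = DDPInstance(
    a=(5, 6, 6, 7, 7, 17),
    b=(3, 5, 6, 6, 7, 21),
    c=(1, 2, 2, 3, 3, 3, 4, 4, 5, 5, 16),
    name="ins2prime",
)

#: Plain-rounded candidate of the same transform — invalid (sums 50/49/51).
SCALED_PLAIN = DDPInstance(
    a=(6, 6, 7, 7, 7, 17),
    b=(4, 5, 6, 6, 7, 21),
    c=(1, 2, 3, 3, 3, 4, 4, 4, 5, 6, 16),
    name="scaled-plain",
)

#: Rounded-up candidate — still invalid (sums 50/50/51).
SCALED_UP = DDPInstance(
    a=(6, 6, 7, 7, 7, 17),
    b=(4, 5, 6, 6, 8, 21),
    c=(1, 2, 3, 3, 3, 4, 4, 4, 5, 6, 16),
    name="scaled-up",
)

#: Value-level referenced-sorting crossover worked example.
RSC_PARENTS = {
    "p1": (1, 3, 2, 1, 3, 4, 2, 2),
    "p2": (1, 2, 2, 2, 4, 3, 3, 1),
    "point": 3,
    "c1": (1, 3, 2, 2, 2, 4, 3, 1),
    "c2": (1, 2, 2, 3, 1, 3, 4, 2),
}

#: Whole-segment mutation examples: (input, expected output).
FLP_EXAMPLE = ((2, 5, 4, 1), (1, 4, 5, 2))
CSH_EXAMPLE = ((2, 5, 4, 1), (5, 4, 1, 2))


def fixtures() -> dict:
    """All packaged fixtures, bit-exact, keyed by name."""
    return {
        "EXAMPLE1": EXAMPLE1,
        "INS2_PRIME": INS2_PRIME,
        "SCALED_PLAIN": SCALED_PLAIN,
        "SCALED_UP": SCALED_UP,
        "SCALED_DOWN": INS2_PRIME,
        "RSC_PARENTS": RSC_PARENTS,
        "FLP_EXAMPLE": FLP_EXAMPLE,
        "CSH_EXAMPLE": CSH_EXAMPLE,
    }
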