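"""Elitist generational genetic algorithm for the double digest problem.

One generation: keep the ``elite_count`` fittest chromosomes unchanged, then
fill the population with offspring of roulette-wheel-selected parent pairs.
A parent pair undergoes crossover with probability ``crossover_prob`` (one
enabled crossover drawn uniformly) or is cloned; each offspring is then
mutated with the scheduled probability (P4X acts on the pair, FLP/CSH act on
mu and nu independently).  The run stops at the first exact solution
(fitness 1) or at ``max_generations``.

Everything is reproducible from ``(instance, config)``: all randomness flows
from one ``numpy`` generator seeded with ``config.seed``, and multi-trial
runs derive per-trial seeds from it deterministically.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import core
from .core import DDPInstance, DigestMapError, InvalidInstanceError, SolutionRecord
from .operators import (
    Chromosome,
    MutationSchedule,
    OperatorSet,
    mutation_probability,
    p4x_mutate,
    flp_mutate,
    csh_mutate,
    pcc_cross,
    rsc_cross,
)

__all__ = ["GAConfig", "GAResult", "TrialStats", "evolve", "run_trials", "derive_trial_seed"]


@dataclass(frozen=True)
class GAConfig:
    """Strategy parameters of the GA (defaults are the package's standard run)."""

    population_size: int = 50
    max_generations: int = 10_000
    crossover_prob: float = 0.85
    operator_set: OperatorSet = field(default_factory=OperatorSet)
    mutation_schedule: MutationSchedule = field(default_factory=MutationSchedule)
    elite_count: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.crossover_prob <= 1):
            raise DigestMapError("crossover_prob must be in (0, 1]")
        if self.population_size < 2:
            raise DigestMapError("population_size must be >= 2")
        if not (1 <= self.elite_count < self.population_size):
            raise DigestMapError("elite_count must satisfy 1 <= elite_count < population_size")
        if not self.operator_set.runnable:
            raise DigestMapError("operator set has no variation operator enabled")


@dataclass
class GAResult:
    best: SolutionRecord
    success: bool
    generations_used: int
    fitness_trace: list
    config: GAConfig
    seed: int
    runtime_s: float = 0.0


@dataclass
class TrialStats:
    n_trials: int
    successes: int
    success_rate: float
    mean_generations: float | None  # over successful trials
    mean_runtime_s: float  # informational only
    per_trial: list  # of GAResult


def _make_mismatch(a, b, c):
    """Fast closure computing the multiset mismatch of a chromosome.

    Cut positions are merged directly from the permuted single digests; the
    realized fragment lengths are compared to sorted(c) by a linear merge.
    """
    n = len(b)
    c_sorted = sorted(c)
    k = len(c_sorted)

    def mismatch(mu, nu):
        pos = []
        s = 0
        for i in mu:
            s += a[i - 1]
            pos.append(s)
        s = 0
        for j in nu[: n - 1]:
            s += b[j - 1]
            pos.append(s)
        pos.sort()
        frags = []
        prev = 0
        for p in pos:
            frags.append(p - prev)
            prev = p
        frags.sort()
        i = j = common = 0
        while i < k and j < k:
            fi = frags[i]
            cj = c_sorted[j]
            if fi == cj:
                common += 1
                i += 1
                j += 1
            elif fi < cj:
                i += 1
            else:
                j += 1
        return 2 * (k - common)

    return mismatch


def evolve(inst: DDPInstance, config: GAConfig = GAConfig()) -> GAResult:
    """Run the GA on one instance; returns the best chromosome ever seen."""
    rep = core.validate(inst)
    if not rep.valid:
        raise InvalidInstanceError(f"instance {inst.name!r} {rep.summary()}")
    t0 = time.perf_counter()
    padded = core.pad_to_canonical(inst)
    a, b, c = padded.a, padded.b, padded.c
    m, n = len(a), len(b)
    rng = np.random.default_rng(config.seed)
    mismatch = _make_mismatch(a, b, c)
    ops = config.operator_set
    cxs = ops.crossovers
    muts = ops.mutations
    P = config.population_size

    def rand_perm(d):
        return tuple(int(x) + 1 for x in rng.permutation(d))

    pop = [(rand_perm(m), rand_perm(n)) for _ in range(P)]
    fits = [1.0 / (1.0 + mismatch(mu, nu)) for mu, nu in pop]
    best_i = max(range(P), key=fits.__getitem__)
    best, best_fit = pop[best_i], fits[best_i]
    trace = [best_fit]
    gen = 0
    found_gen = 0 if best_fit == 1.0 else None

    while found_gen is None and gen < config.max_generations:
        gen += 1
        p_mut = mutation_probability(gen, m, n, config.mutation_schedule) if muts else 0.0
        order = sorted(range(P), key=fits.__getitem__, reverse=True)
        newpop = [pop[i] for i in order[: config.elite_count]]
        need = P - len(newpop)
        probs = np.asarray(fits)
        parents = rng.choice(P, size=2 * ((need + 1) // 2), p=probs / probs.sum())
        children = []
        for x in range(0, len(parents), 2):
            pa = pop[int(parents[x])]
            pb = pop[int(parents[x + 1])]
            if cxs and rng.random() < config.crossover_prob:
                op = cxs[int(rng.integers(len(cxs)))] if len(cxs) > 1 else cxs[0]
                if op == "rsc" and (m < 2 or n < 2):
                    op = "pcc"  # RSC needs a cut point in both components
                ca, cb = Chromosome(*pa), Chromosome(*pb)
                if op == "pcc":
                    o1, o2 = pcc_cross(ca, cb)
                else:
                    o1, o2 = rsc_cross(ca, cb, rng)
                children.append((o1.mu, o1.nu))
                children.append((o2.mu, o2.nu))
            else:
                children.append(pa)
                children.append(pb)
        for mu, nu in children[:need]:
            if muts:
                op = muts[int(rng.integers(len(muts)))] if len(muts) > 1 else muts[0]
                if op == "p4x":
                    if m >= 2 and n >= 2 and rng.random() < p_mut:
                        ch = p4x_mutate(Chromosome(mu, nu), rng)
                        mu, nu = ch.mu, ch.nu
                else:
                    fn = flp_mutate if op == "flp" else csh_mutate
                    if m >= 2 and rng.random() < p_mut:
                        mu = fn(mu, rng)
                    if n >= 2 and rng.random() < p_mut:
                        nu = fn(nu, rng)
            newpop.append((mu, nu))
        pop = newpop
        fits = [1.0 / (1.0 + mismatch(mu, nu)) for mu, nu in pop]
        gi = max(range(P), key=fits.__getitem__)
        if fits[gi] > best_fit:
            best, best_fit = pop[gi], fits[gi]
        if best_fit == 1.0:
            found_gen = gen
        trace.append(best_fit)

    success = found_gen is not None
    record = core.solution_record(best[0], best[1], padded, generation_found=found_gen or gen)
    assert record.fitness == best_fit  # cache coherence with the fast path
    return GAResult(
        best=record,
        success=success,
        generations_used=found_gen if success else gen,
        fitness_trace=trace,
        config=config,
        seed=config.seed,
        runtime_s=time.perf_counter() - t0,
    )


def derive_trial_seed(base_seed: int, trial: int) -> int:
    """Deterministic, well-mixed per-trial seed (counter-based derivation)."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(trial),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_trials(inst: DDPInstance, config: GAConfig, n_trials: int) -> TrialStats:
    """Repeat :func:`evolve` with independently derived seeds and aggregate."""
    if n_trials < 1:
        raise DigestMapError("n_trials must be >= 1")
    results = []
    for t in range(n_trials):
        cfg = replace(config, seed=derive_trial_seed(config.seed, t))
        results.append(evolve(inst, cfg))
    succ = [r for r in results if r.success]
    return TrialStats(
        n_trials=n_trials,
        successes=len(succ),
        success_rate=len(succ) / n_trials,
        mean_generations=(sum(r.generations_used for r in succ) / len(succ)) if succ else None,
        mean_runtime_s=sum(r.runtime_s for r in results) / n_trials,
        per_trial=results,
    )
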