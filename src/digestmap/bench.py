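"""Benchmark sweeps: GA success rate as a function of instance hardness.

The hardness knob is rho_C = max c_i, the longest double-digest fragment.
For a fixed number of fragments and total length, small rho_C forces many
near-equal fragment lengths, which makes multiset-equal rearrangements (and
hence exact solutions) dense and the GA's job easy; large rho_C makes
solutions sparse.  The sweep draws fresh random instances per trial at each
rho_C cap and reports the success rate under a capped generation budget.

A cap can be arithmetically infeasible (rho_C * (m+n-1) < L); such points
are reported with ``feasible = False`` and excluded from the trend
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .engine import GAConfig, derive_trial_seed, evolve
from .instances import GeneratorSpec, random_instance

__all__ = ["SweepRow", "sweep_rho", "success_trend"]


@dataclass
class SweepRow:
    rho_c_max: int
    feasible: bool
    n_trials: int
    successes: int
    success_rate: float | None
    mean_generations: float | None


def sweep_rho(
    m: int,
    n: int,
    total_length: int,
    rho_values,
    n_trials: int = 20,
    config: GAConfig = None,
    generation_budget: int = 400,
    seed: int = 0,
) -> list:
    """One :class:`SweepRow` per rho_C cap, fresh instances every trial."""
    if config is None:
        config = GAConfig()
    config = replace(config, max_generations=generation_budget)
    rows = []
    for ridx, rho in enumerate(rho_values):
        spec = GeneratorSpec(m=m, n=n, total_length=total_length, rho_c_max=int(rho))
        try:
            spec.check_feasible()
        except Exception:
            rows.append(SweepRow(int(rho), False, 0, 0, None, None))
            continue
        successes = 0
        gens = []
        for t in range(n_trials):
            trial_seed = derive_trial_seed(seed, ridx * 100_000 + t)
            rng = np.random.default_rng(trial_seed)
            inst, _truth = random_instance(spec, rng)
            res = evolve(inst, replace(config, seed=derive_trial_seed(trial_seed, 1)))
            if res.success:
                successes += 1
                gens.append(res.generations_used)
        rows.append(
            SweepRow(
                rho_c_max=int(rho),
                feasible=True,
                n_trials=n_trials,
                successes=successes,
                success_rate=successes / n_trials,
                mean_generations=(sum(gens) / len(gens)) if gens else None,
            )
        )
    return rows


def success_trend(rows) -> float:
    """Spearman rank correlation of success rate against rho_C.

    Computed over feasible sweep points only.  A constant success-rate
    profile has no defined rank correlation; it is reported as 0.0 (a flat
    profile is trivially non-increasing).
    """
    pts = [(r.rho_c_max, r.success_rate) for r in rows if r.feasible]
    if len(pts) < 2:
        raise ValueError("need at least two feasible sweep points")
    xs, ys = zip(*pts)
    if len(set(ys)) == 1:
        return 0.0
    rho, _ = stats.spearmanr(xs, ys)
    return float(rho)
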