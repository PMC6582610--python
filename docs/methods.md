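# Methods

## Model

A DDP instance is three fragment-length vectors a (m entries), b (n
entries), c (k entries) of non-negative integers with Σa = Σb = Σc = L.
Lengths are treated as exact integers — there is no measurement-noise model
beyond the multiset mismatch itself, and no nucleotide-level information.

Prefix sums of an ordered fragment vector are cut positions; step
differences invert them. The double digest sequence DDS(a, b) of *ordered*
a and b merges the m cut positions of a with the n−1 interior cut positions
of b, sorts, and differences. It always has m + n − 1 entries; a zero entry
appears exactly where both enzymes cut the same site. Observed data hides
those zeros (a zero-length fragment is invisible on a gel), which is why a
real c may have k < m + n − 1. Preprocessing restores the canonical shape:
if k < m + n − 1, append δ = m + n − 1 − k zeros to c; if k > m + n − 1
(an experimental artefact), append zeros to the shorter of a and b, padding
a on ties. Padding never changes totals, and the padded zeros are rendered
explicitly (as radial ticks) in charts.

A candidate solution is a pair of permutations (μ, ν) acting by gather,
`permute(v, p)[i] = v[p(i)]`, in 1-based one-line notation. The fitness
1/(1 + |DDS(aᵘ, bᵛ) ⊕ c|) uses the multiset symmetric difference ⊕ computed
on exact integers; it lies in (0, 1] and equals 1 iff the map is exact. For
an exact solution the arrangement π of c is recovered by stably sorting the
realized sequence and pairing positions with c's indices in (value, index)
order — deterministic even though π is not unique under tied lengths.

The gather convention is a deliberate choice: under it the worked
four-fragment example verifies exactly with ν = (3,1,2,4), and the
companion μ is (1,4,3,2) — the exhaustive oracle confirms that pair (and 63
others, 32 up to mirror symmetry) solves the instance.

Reading a map from the other end of the molecule reverses both orderings;
exact solutions therefore come in mirror pairs, an invariant the oracle and
GA tests both check.

### Map comparison

`map_distance` quantifies disagreement between two maps of the same
molecule: interior cut positions (prefix sums of each realized double
digest, excluding L) are matched in sorted order and their L1 displacement
is divided by L. This is a formalization of "total gap length between
mis-aligned fragments, relative to the molecule" — the package's own
operationalization; it is 0 iff the cut sets coincide and is symmetric. It
is reported as a diagnostic only and carries no acceptance weight.

## Genetic algorithm

Chromosome: (μ, ν) ∈ S_m × S_n, initialized uniformly at random.
Defaults (the package's standard run): population 50, generation cap
10 000, crossover probability 0.85, one elite, mutation probability ramping
linearly from 2/(m+n) to 0.55 over 200-generation cycles.

One generation:

1. copy the `elite_count` fittest chromosomes unchanged;
2. draw parent pairs by roulette-wheel selection (probability ∝ fitness);
3. with probability `crossover_prob` apply one enabled crossover (drawn
   uniformly when several are enabled), else clone the parents;
4. mutate each offspring: one enabled mutation is drawn uniformly; P4X is
   applied to the pair with the scheduled probability, FLP/CSH are applied
   to μ and ν independently, each with the scheduled probability.

The run stops at the first fitness-1 chromosome or at the cap; the
generation counter starts at 0 for the initial population. Best-so-far
fitness is non-decreasing by construction (elitism), and every reported
best is re-scored from scratch by the slow path before it is returned.

Operator details and conventions, where the design was genuinely open:

* **PCC** composes pairwise: offspring (μ₁∘μ₂, ν₁∘ν₂) and (μ₂∘μ₁, ν₂∘ν₁),
  (p∘q)(i) = p(q(i)).
* **RSC** draws its cut point independently for μ and ν, uniform on
  1..degree−1, shared by the two offspring of that component. The suffix is
  rearranged by *referenced sorting*: the rightmost subsequence of the
  co-parent realizing the suffix's multiset (greedy right-to-left
  matching). Right-to-left is forced by the published worked example —
  both printed offspring chains are reproduced only under rightmost
  matching; leftmost fails both. On permutations (all symbols distinct) the
  rearrangement is exact, so offspring are always bijections.
* **P4X** draws its two positions per component without replacement, so a
  mutation never degenerates to a no-op.
* **FLP/CSH** draw segment endpoints i < j uniformly over all pairs; CSH
  rotates left by one, matching the printed example.
* The mutation-probability floor 2/(m+n) is clamped to the ceiling for
  degenerate degrees (m + n < 4, where the floor would exceed 0.55), so the
  within-cycle increment is non-negative for every m + n ≥ 2. The ceiling
  0.55 (not 0.45) exists precisely so the smallest practical case
  m = n = 2, whose floor is 0.5, still ramps upward.
* Benchmark operator combinations: the six crossover × mutation pairs plus
  the everything-enabled set. Single-variation-operator sets are accepted
  by the API and CLI, but crossover-only RSC is excluded from the benchmark
  suite by design: referenced sorting of identical parents is the identity,
  so once the population converges the configuration is absorbing and
  stalls on sparse-solution instances.

Per-trial seeds derive from the base seed via `numpy` `SeedSequence`
spawn keys, so trials are independent and each trial is individually
replayable.

## Random instances

The generator samples cut positions, not fragment lengths, so every
instance is valid by construction and ships with its generating orderings
as a certified ground truth (fitness 1 after padding).

* Unconstrained: m−1 (resp. n−1) distinct interior cut sites per enzyme,
  uniform from 1..L−1. A site shared between the enzymes is allowed and
  produces a coincident cut; the emitted c drops the zero-length fragments,
  exactly as a gel would.
* Capped ρ_C: the double-digest fragment lengths are drawn as a uniform
  random composition of L into m + n − 1 parts in [1, ρ_C], sampled exactly
  with a dynamic-programming count table, and the interior cut sites are
  then split at random between the enzymes (m−1 to A, n−1 to B). Exact
  conditional sampling is used because naive rejection on uniform cuts has
  vanishing acceptance for tight caps — at L = 300 and k = 11 the expected
  maximum fragment is ≈ 82, so caps near 30 would essentially never be
  accepted by rejection.

A cap is *infeasible* when ρ_C · (m + n − 1) < L; the generator raises and
the bench marks the sweep point infeasible rather than silently relaxing L.
Emitted a and b are shuffled; c is sorted ascending, the way fragment
lengths come off a gel.

What the generator does **not** emulate: measurement error in fragment
lengths, missing or merged gel bands, partial digestion. Passing tests on
generated instances therefore demonstrate correctness of the combinatorial
reconstruction, not robustness to noisy sizing data.

## Scaling-rounding-adjusting

For instances whose lengths are large (slow, sparse-solution search), the
transform multiplies all lengths by a factor and rounds (half away from
zero; ties are not specified by convention elsewhere, so the engineering
rule is fixed here). Rounding usually breaks Σa = Σb = Σc, so two adjusted
candidates re-round at x ± t (default t = 0.1, valid domain
[0.0001, 0.4999]). Candidates are tried plain → up → down (configurable)
and the first valid one is selected; all three sum-triples are reported for
audit. The default factor is the smallest power of ten that keeps the
shortest double-digest fragment ≥ 1. A solution of the scaled surrogate is
an approximate map of the original; `map_distance` quantifies the residual
displacement.

## Hardness and the ρ_C sweep

For fixed k and L, small ρ_C = max cᵢ forces near-equal fragment lengths,
making multiset-equal rearrangements — hence exact solutions — dense; large
ρ_C makes them sparse. The bench sweeps a ρ_C cap at fixed (m, n, L) with
fresh random instances per trial and a capped generation budget, and
summarizes the trend as the Spearman rank correlation of success rate
against ρ_C over the feasible sweep points. A flat success profile has no
defined rank correlation and is reported as 0 (trivially non-increasing).
Default sweep in the acceptance suite: m = n = 6, L = 300,
caps {10, 30, 60, 100}, 20 trials per point, 400-generation budget — sizes
chosen so the whole sweep runs in seconds while the trend is already
resolved; the cap 10 point is arithmetically infeasible (11 · 10 < 300) and
is reported as such.

## Numerical and determinism notes

* All sorts are stable; ties in π-extraction break by ascending original
  index.
* Fitness values are exact rationals represented in floating point
  (denominator ≤ 1 + 2k, no rounding issues at these magnitudes).
* The fast GA scoring path (merged prefix sums, linear multiset merge) is
  cross-checked in tests against the definitional slow path for every
  reported best chromosome.
* The exhaustive oracle enumerates S_m × S_n in lexicographic order behind
  a size guard (default 10⁷ chromosomes); its job is certainty, not speed.
* CLI artifacts embed a manifest (command, config, seed, input digest);
  reruns with equal manifests produce byte-identical outputs except for the
  timestamp. Wall-clock runtimes are recorded as information only and no
  test or acceptance quantity depends on them.

## Known limitations

* Exact integer lengths only; no error-tolerant matching beyond the
  multiset mismatch.
* The GA is a heuristic: failure to find a solution within the cap does not
  certify unsolvability (use the oracle for small instances).
* `map_distance` compares cut sets position-wise after sorting; it does not
  attempt fragment-identity alignment between maps.
* The benchmark statistics here are desk-scale (20 trials per combination);
  they estimate, not exhaust, the run-to-run distribution.
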