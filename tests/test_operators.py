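"""Genetic operators: printed worked examples, laws, and distributions."""

import numpy as np
import pytest
from scipy import stats

from digestmap.core import Chromosome, DigestMapError
from digestmap.operators import (
    BENCHMARK_OPERATOR_SETS,
    MutationSchedule,
    OperatorSet,
    csh_mutate,
    cyclic_shift_segment,
    flip_segment,
    flp_mutate,
    mutation_probability,
    p4x_mutate,
    pcc_cross,
    refer_sort,
    rsc_cross,
    rsc_cross_sequences,
    rws_select,
)


# --- referenced sorting ----------------------------------------------------


@pytest.mark.parametrize(
    "target, reference, expected",
    [
        ((1, 3, 4, 2, 2), (1, 2, 2, 2, 4, 3, 3, 1), (2, 2, 4, 3, 1)),
        ((2, 4, 3, 3, 1), (1, 3, 2, 1, 3, 4, 2, 2), (3, 1, 3, 4, 2)),
        ((1, 2, 3), (1, 2, 3), (1, 2, 3)),
    ],
)
def test_refer_sort_worked_examples(target, reference, expected):
    assert refer_sort(target, reference) == expected


def test_refer_sort_multiplicity_shortfall():
    with pytest.raises(DigestMapError):
        refer_sort((2, 2), (1, 2, 3))


def test_rsc_value_level_worked_example():
    c1, c2 = rsc_cross_sequences(
        (1, 3, 2, 1, 3, 4, 2, 2), (1, 2, 2, 2, 4, 3, 3, 1), 3
    )
    assert c1 == (1, 3, 2, 2, 2, 4, 3, 1)
    assert c2 == (1, 2, 2, 3, 1, 3, 4, 2)


def test_rsc_identical_parents_fixed_point(rng):
    ch = Chromosome((3, 1, 4, 2), (2, 4, 1, 3))
    o1, o2 = rsc_cross(ch, ch, rng)
    assert (o1.mu, o1.nu) == (ch.mu, ch.nu)
    assert (o2.mu, o2.nu) == (ch.mu, ch.nu)


def test_rsc_offspring_are_bijections(rng):
    for _ in range(50):
        mu1 = tuple(int(x) + 1 for x in rng.permutation(6))
        mu2 = tuple(int(x) + 1 for x in rng.permutation(6))
        nu1 = tuple(int(x) + 1 for x in rng.permutation(5))
        nu2 = tuple(int(x) + 1 for x in rng.permutation(5))
        o1, o2 = rsc_cross(Chromosome(mu1, nu1), Chromosome(mu2, nu2), rng)
        for o in (o1, o2):
            assert sorted(o.mu) == [1, 2, 3, 4, 5, 6]
            assert sorted(o.nu) == [1, 2, 3, 4, 5]


# --- composition crossover -------------------------------------------------


def test_pcc_identity_law():
    ch = Chromosome((2, 3, 1), (3, 1, 2))
    ident = Chromosome((1, 2, 3), (1, 2, 3))
    o1, _ = pcc_cross(ch, ident)
    assert (o1.mu, o1.nu) == (ch.mu, ch.nu)


def test_pcc_involution_and_inverse_pair():
    o1, _ = pcc_cross(Chromosome((2, 1), (2, 1)), Chromosome((2, 1), (2, 1)))
    assert o1.mu == (1, 2)
    o1, o2 = pcc_cross(Chromosome((2, 3, 1), (1, 2, 3)), Chromosome((3, 1, 2), (1, 2, 3)))
    assert o1.mu == (1, 2, 3) and o2.mu == (1, 2, 3)


# --- mutations -------------------------------------------------------------


def test_flip_and_shift_whole_segment_examples():
    assert flip_segment((2, 5, 4, 1), 0, 3) == (1, 4, 5, 2)
    assert cyclic_shift_segment((2, 5, 4, 1), 0, 3) == (5, 4, 1, 2)


def test_flip_length2_is_transposition_and_involution():
    assert flip_segment((1, 2, 3), 0, 1) == (2, 1, 3)
    assert flip_segment(flip_segment((4, 2, 3, 1), 1, 3), 1, 3) == (4, 2, 3, 1)


def test_cyclic_shift_order():
    s = (5, 3, 1, 2, 4)
    out = s
    for _ in range(3):  # rotating a length-3 segment 3 times is the identity
        out = cyclic_shift_segment(out, 1, 3)
    assert out == s


@pytest.mark.parametrize("mutate", [flp_mutate, csh_mutate])
def test_segment_mutations_preserve_bijection(mutate, rng):
    for _ in range(100):
        p = tuple(int(x) + 1 for x in rng.permutation(7))
        q = mutate(p, rng)
        assert sorted(q) == list(range(1, 8))
    with pytest.raises(DigestMapError):
        mutate((1,), rng)


def test_p4x_touches_two_loci_per_component(rng):
    ch = Chromosome(tuple(range(1, 8)), tuple(range(1, 6)))
    for _ in range(50):
        out = p4x_mutate(ch, rng)
        assert sum(a != b for a, b in zip(out.mu, ch.mu)) == 2
        assert sum(a != b for a, b in zip(out.nu, ch.nu)) == 2
    forced = p4x_mutate(Chromosome((1, 2), (1, 2)), rng)
    assert forced.mu == (2, 1) and forced.nu == (2, 1)


# --- mutation schedule -----------------------------------------------------


def test_schedule_endpoints():
    assert mutation_probability(0, 2, 2) == pytest.approx(0.5)
    assert mutation_probability(200, 2, 2) == pytest.approx(0.5)  # cycle restarts
    for m, n in [(2, 2), (5, 5), (10, 10), (3, 17)]:
        assert mutation_probability(199, m, n) == pytest.approx(0.55)
    assert mutation_probability(0, 10, 10) == pytest.approx(0.1)


def test_schedule_nondecreasing_within_cycle():
    sched = MutationSchedule()
    for m, n in [(2, 2), (1, 1), (6, 6), (20, 30)]:
        probs = [mutation_probability(g, m, n, sched) for g in range(200)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert max(probs) <= 0.55 + 1e-12


# --- selection -------------------------------------------------------------


def test_rws_uniform_fitnesses_chi2(rng):
    draws = rws_select([1.0] * 5, 10_000, rng)
    counts = np.bincount(draws, minlength=5)
    assert stats.chisquare(counts).pvalue > 0.01


def test_rws_proportionality(rng):
    draws = rws_select([3.0, 1.0], 40_000, rng)
    freq = np.mean(draws == 0)
    sigma = np.sqrt(0.75 * 0.25 / 40_000)
    assert abs(freq - 0.75) < 3 * sigma


def test_rws_input_contracts(rng):
    with pytest.raises(DigestMapError):
        rws_select([], 1, rng)
    with pytest.raises(DigestMapError):
        rws_select([1.0, 0.0], 1, rng)


# --- operator sets ---------------------------------------------------------


def test_operator_set_parsing():
    assert OperatorSet.from_names("all") == OperatorSet()
    assert OperatorSet.from_names("rws,pcc").crossovers == ("pcc",)
    assert OperatorSet.from_names(["RSC", "flp"]) == OperatorSet(("rsc",), ("flp",))
    with pytest.raises(DigestMapError):
        OperatorSet.from_names("rws")  # no variation operator
    with pytest.raises(DigestMapError):
        OperatorSet.from_names("pcx")


def test_benchmark_sets_cover_all_pairs():
    labels = {s.label() for s in BENCHMARK_OPERATOR_SETS}
    assert "all" in labels and len(BENCHMARK_OPERATOR_SETS) == 7
    assert all(s.runnable for s in BENCHMARK_OPERATOR_SETS)
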