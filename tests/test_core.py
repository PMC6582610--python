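"""Digest-map vector arithmetic: worked examples and error contracts."""

import pytest

from digestmap import core
from digestmap.core import (
    DDPInstance,
    DigestMapError,
    InvalidInstanceError,
    SizeMismatchError,
    accumulative_sum,
    combine,
    dds,
    extract_pi,
    fitness_of,
    map_distance,
    multiset_mismatch,
    pad_to_canonical,
    permute,
    solution_record,
    step_difference,
    validate,
)


@pytest.mark.parametrize(
    "v, p, expected",
    [
        ((2, 2, 3, 4), (3, 1, 2, 4), (3, 2, 2, 4)),
        ((1, 2, 3, 5), (1, 2, 3, 4), (1, 2, 3, 5)),
        ((1, 2, 3, 5), (1, 4, 3, 2), (1, 5, 3, 2)),
    ],
)
def test_permute_gather_convention(v, p, expected):
    assert permute(v, p) == expected


def test_permute_degree_mismatch():
    with pytest.raises(SizeMismatchError):
        permute((1, 2, 3), (2, 1))


def test_permute_rejects_non_bijection():
    with pytest.raises(DigestMapError):
        permute((1, 2, 3), (1, 1, 2))


@pytest.mark.parametrize(
    "v, expected",
    [
        ((1, 5, 3, 2), (1, 6, 9, 11)),
        ((7,), (7,)),
        ((0, 0, 5), (0, 0, 5)),
    ],
)
def test_accumulative_sum(v, expected):
    assert accumulative_sum(v) == expected


def test_accumulative_sum_empty():
    with pytest.raises(DigestMapError):
        accumulative_sum(())


@pytest.mark.parametrize(
    "v, expected",
    [
        ((1, 3, 5, 6, 7, 9, 11), (1, 2, 2, 1, 1, 2, 2)),
        ((5,), (5,)),
        # repeated cut position at 7 yields a zero-length fragment
        ((2, 3, 5, 7, 7, 10, 11), (2, 1, 2, 2, 0, 3, 1)),
    ],
)
def test_step_difference(v, expected):
    assert step_difference(v) == expected


def test_step_difference_rejects_decreasing():
    with pytest.raises(DigestMapError):
        step_difference((3, 2))


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((1, 5, 3, 2), (3, 2, 2, 4), (1, 6, 9, 11, 3, 5, 7)),
        ((11,), (11,), (11,)),
        ((1, 1), (1, 1), (1, 2, 1)),
    ],
)
def test_combine(a, b, expected):
    assert combine(a, b) == expected


def test_combine_unequal_totals():
    with pytest.raises(InvalidInstanceError):
        combine((1, 2), (4,))


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((1, 5, 3, 2), (3, 2, 2, 4), (1, 2, 2, 1, 1, 2, 2)),
        ((2, 5, 3, 1), (3, 2, 2, 4), (2, 1, 2, 2, 0, 3, 1)),
        # both enzymes cut at position 1: coincident site, zero fragment
        ((1, 1), (1, 1), (1, 0, 1)),
    ],
)
def test_dds(a, b, expected):
    assert dds(a, b) == expected


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((2, 1, 2, 2, 0, 3, 1), (1, 1, 1, 2, 2, 2, 2), 4),
        ((5, 1, 3), (5, 1, 3), 0),
        ((1, 2, 2), (1, 2, 3), 2),
    ],
)
def test_multiset_mismatch(x, y, expected):
    assert multiset_mismatch(x, y) == expected
    assert multiset_mismatch(y, x) == expected  # symmetric


def test_fitness_exact_and_near(example1):
    assert fitness_of((1, 4, 3, 2), (3, 1, 2, 4), example1) == 1.0
    assert fitness_of((2, 4, 3, 1), (3, 1, 2, 4), example1) == pytest.approx(0.2)


def test_fitness_requires_canonical_k():
    inst = DDPInstance(a=(1, 1), b=(1, 1), c=(1, 1))  # k=2 < m+n-1=3
    with pytest.raises(DigestMapError):
        fitness_of((1, 2), (1, 2), inst)


def test_validate_printed_instances(ins2prime):
    rep = validate(ins2prime)
    assert rep.valid and rep.sum_a == rep.sum_b == rep.sum_c == 48
    bad = DDPInstance(
        a=(6, 6, 7, 7, 7, 17), b=(4, 5, 6, 6, 7, 21), c=(1, 2, 3, 3, 3, 4, 4, 4, 5, 6, 16)
    )
    rep = validate(bad)
    assert not rep.valid
    assert (rep.sum_a, rep.sum_b, rep.sum_c) == (50, 49, 51)
    assert validate(DDPInstance(a=(1,), b=(1,), c=(1,))).valid


def test_pad_to_canonical(ins2prime):
    inst = DDPInstance(a=(1, 1), b=(1, 1), c=(1, 1))
    padded = pad_to_canonical(inst)
    assert padded.c == (1, 1, 0)
    assert multiset_mismatch(dds((1, 1), (1, 1)), padded.c) == 0
    assert pad_to_canonical(ins2prime) is ins2prime  # 11 == 6+6-1 already
    # k too long: the shorter single digest gets the zeros (tie pads a)
    long_c = DDPInstance(a=(2, 2), b=(4,), c=(2, 1, 1))
    padded = pad_to_canonical(long_c)
    assert padded.b == (4, 0) and padded.k == padded.m + padded.n - 1
    with pytest.raises(InvalidInstanceError):
        pad_to_canonical(DDPInstance(a=(2,), b=(3,), c=(2,)))


def test_extract_pi_stable(example1):
    pi = extract_pi((1, 4, 3, 2), (3, 1, 2, 4), example1)
    assert pi == (1, 4, 5, 2, 3, 6, 7)
    assert permute(example1.c, pi) == dds((1, 5, 3, 2), (3, 2, 2, 4))


def test_extract_pi_identity_when_already_equal():
    inst = DDPInstance(a=(1, 2), b=(3,), c=(1, 2))
    assert extract_pi((1, 2), (1,), inst) == (1, 2)


def test_extract_pi_rejects_inexact(example1):
    with pytest.raises(DigestMapError):
        extract_pi((2, 4, 3, 1), (3, 1, 2, 4), example1)


def test_solution_record_roundtrip(example1):
    rec = solution_record((1, 4, 3, 2), (3, 1, 2, 4), example1, generation_found=7)
    assert rec.mismatch == 0 and rec.fitness == 1.0 and rec.generation_found == 7
    assert permute(example1.c, rec.pi) == rec.dds


def test_map_distance(example1):
    rec = solution_record((1, 4, 3, 2), (3, 1, 2, 4), example1)
    assert map_distance(rec, rec, example1.total_length) == 0.0
    # u=(2,5) vs w=(3,5) on a length-10 molecule: displacement 1/10
    i1 = DDPInstance(a=(2, 3, 5), b=(10,), c=(2, 3, 5))
    i2 = DDPInstance(a=(3, 2, 5), b=(10,), c=(3, 2, 5))
    r1 = solution_record((1, 2, 3), (1,), pad_to_canonical(i1))
    r2 = solution_record((1, 2, 3), (1,), pad_to_canonical(i2))
    assert map_distance(r1, r2, 10) == pytest.approx(0.1)
    with pytest.raises(SizeMismatchError):
        map_distance(r1, rec, 10)


def test_mirror_of_exact_solution_is_exact(example1):
    mu, nu = (1, 4, 3, 2), (3, 1, 2, 4)
    assert fitness_of(core.mirror(mu), core.mirror(nu), example1) == 1.0


def test_negative_lengths_rejected():
    with pytest.raises(DigestMapError):
        DDPInstance(a=(1, -2), b=(-1,), c=(-1,))
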