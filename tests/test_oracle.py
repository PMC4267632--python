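"""Enumeration references and the synthetic fixture generator."""

import pytest

from costruct.oracle import (FixtureSpec, count_structures_recurrence,
                             enumerate_common, enumerate_structures,
                             make_fixture)
from conftest import random_seq


def test_enumerate_trivial(params):
    st = enumerate_structures("AAAA", params)
    assert len(st) == 1 and st[0] == ((), 0)
    # any pair in GCGC would close a loop shorter than the minimum
    st = enumerate_structures("GCGC", params)
    assert [pairs for pairs, _ in st] == [()]


def test_enumeration_count_matches_recurrence(params, rng):
    for seq in ["GGGAAAACCC"] + [random_seq(rng, rng.randint(6, 12))
                                 for _ in range(10)]:
        assert len(enumerate_structures(seq, params)) == \
            count_structures_recurrence(seq, params)


def test_enumerate_guard(params):
    with pytest.raises(ValueError):
        enumerate_structures("A" * 15, params)
    with pytest.raises(ValueError):
        enumerate_common("A" * 11, "AAA", params)


def test_enumerate_common_symmetry(params):
    s1, s2 = "GGCGAAAACGCC", "GGGAAAACCC"
    s1 = s1[:10]
    _, e12 = enumerate_common(s1, s2, params, "dynalign2")
    _, e21 = enumerate_common(s2, s1, params, "dynalign2")
    assert e12 == e21


def test_enumerate_common_identical(params):
    seq = "GGGAAAACCC"
    from costruct import fold_single
    cs, e = enumerate_common(seq, seq, params, "dynalign2")
    assert e == 2 * fold_single(seq, params).mfe_t
    assert cs.breakdown.n_gap == 0


def test_fixture_determinism():
    spec = FixtureSpec(seed=11, insertion=(2, 4, 4))
    a = make_fixture(spec)
    b = make_fixture(spec)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].pairs2 == b[2].pairs2


def test_fixture_no_insertion_zero_mutation():
    s1, s2, ref, aln = make_fixture(FixtureSpec(seed=3, mutation_rate=0.0))
    assert s1 == s2
    assert ref.domains == []
    assert ref.pairs1 == ref.pairs2


def test_fixture_domain_length():
    stem, loop = 4, 5
    s1, s2, ref, aln = make_fixture(FixtureSpec(seed=5, insertion=(2, stem, loop)))
    assert len(ref.domains) == 1
    assert ref.domains[0].length == 2 * stem + loop
    assert len(s2) - len(s1) == 2 * stem + loop
    # planted pairs recorded inside the domain interval
    assert len(ref.domain_pairs(2)) == stem


def test_fixture_unsatisfiable():
    with pytest.raises(ValueError):
        FixtureSpec(seed=1, insertion=(3, 4, 4))
    with pytest.raises(ValueError):
        FixtureSpec(seed=1, n_stems=0)
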