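"""Single-sequence fold vs the exhaustive enumeration reference."""

import pytest

from costruct import fold_single, filter_pairs
from costruct.thermo import INF
from costruct.oracle import enumerate_structures
from costruct.singlefold import mfe_structure
from conftest import random_seq


def test_unpairable_sequence(params):
    t = fold_single("AAAA", params)
    assert t.mfe == 0.0
    assert not (t.v < INF).any()


def test_simple_hairpin_mfe(params):
    # GGGGAAAACCCC folds into a 4-pair helix: 3 GC/GC stacks + loop of 4
    from costruct.thermo import PAIRS
    gc = list(PAIRS).index("GC")
    expect = 3 * params.stack_table[gc, gc] + params.hairpin_init[4]
    t = fold_single("GGGGAAAACCCC", params)
    assert t.mfe_t == expect
    assert mfe_structure(t, params) == [(1, 12), (2, 11), (3, 10), (4, 9)]


def test_invalid_character(params):
    with pytest.raises(ValueError):
        fold_single("ACGN", params)


def test_mfe_matches_enumeration(params, rng):
    for _ in range(30):
        seq = random_seq(rng, rng.randint(5, 12))
        best = min(e for _, e in enumerate_structures(seq, params))
        assert fold_single(seq, params).mfe_t == best


def test_mfe_monotone_under_extension(params, rng):
    # appending nucleotides never raises the MFE (exterior unpaired is free)
    for _ in range(10):
        seq = random_seq(rng, rng.randint(6, 11))
        m0 = fold_single(seq, params).mfe_t
        m1 = fold_single(seq + rng.choice("ACGU"), params).mfe_t
        assert m1 <= m0


def test_filter_limits(params, rng):
    seq = "GGGGAAAACCCC"
    t = fold_single(seq, params)
    full = filter_pairs(seq, t, 1.0, params).copy()
    assert (full == (t.v < INF)).all()
    st = enumerate_structures(seq, params)
    mfe = min(e for _, e in st)
    mfe_pairs = {q for pairs, e in st if e == mfe for q in pairs}
    tight = filter_pairs(seq, t, 0.0, params)
    got = {(i, j) for i in range(1, 13) for j in range(i + 1, 13)
           if tight[i, j]}
    assert got == mfe_pairs


def test_filter_window_matches_enumeration(params, rng):
    for _ in range(10):
        seq = random_seq(rng, 12)
        st = enumerate_structures(seq, params)
        mfe = min(e for _, e in st)
        thr = mfe + round(0.2 * abs(mfe))
        expect = {q for pairs, e in st if e <= thr for q in pairs}
        t = fold_single(seq, params)
        mask = filter_pairs(seq, t, 0.2, params)
        got = {(i, j) for i in range(1, 13) for j in range(i + 1, 13)
               if mask[i, j]}
        assert got == expect


def test_negative_window_rejected(params):
    t = fold_single("GGGGAAAACCCC", params)
    with pytest.raises(ValueError):
        filter_pairs("GGGGAAAACCCC", t, -0.1, params)
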