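"""Energy model: table lookups, motif dispatch, and bundle round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from costruct import load_params, is_canonical
from costruct.thermo import (INF, BundleFormatError, encode, end_penalty,
                             hairpin_energy, hairpin_energy_t, motif_energy,
                             motif_energy_t, save_params, stack_energy,
                             stack_energy_t)


def test_shipped_defaults(params):
    assert params.gap_penalty == 4       # 0.4 kcal/mol in tenths
    assert params.domain_opening == 5    # 0.5 kcal/mol
    assert params.domain_elongation == 1  # 0.1 kcal/mol


@pytest.mark.parametrize("b1,b2,expect", [
    ("G", "C", True), ("C", "G", True), ("A", "U", True), ("U", "A", True),
    ("G", "U", True), ("U", "G", True),
    ("A", "G", False), ("A", "A", False), ("C", "U", False),
])
def test_canonical_pairs(b1, b2, expect):
    assert is_canonical(b1, b2) is expect


def test_canonical_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        is_canonical("N", "A")


def test_end_penalty(params):
    assert end_penalty("GAAAC", 1, 5, params) == 0.0
    assert end_penalty("AAAAU", 1, 5, params) == params.au_gu_end_penalty / 10
    assert end_penalty("GAAAU", 1, 5, params) == params.au_gu_end_penalty / 10
    with pytest.raises(ValueError):
        end_penalty("AAAAG", 1, 5, params)


def test_hairpin_energy(params):
    # loop of 4 closed by G-C: initiation only, no end penalty
    assert hairpin_energy("GAAAAC", 1, 6, params) == params.hairpin_init[4] / 10
    # A-U closure adds the end penalty
    au = hairpin_energy("AAAAAU", 1, 6, params)
    assert au == (params.hairpin_init[4] + params.au_gu_end_penalty) / 10
    # loop below the minimum is forbidden, not an exception
    assert hairpin_energy("GAAC", 1, 4, params) == math.inf


def test_motif_dispatch(params):
    # stack: direct table lookup (G-C closing, C-G inner)
    gc_cg = motif_energy("GCCGGC", 1, 2, 6, 5, params)
    assert gc_cg == params.stack_table[2, 1] / 10  # PAIRS order: GC, CG
    # symmetric 1x1 internal loop: initiation + both end penalties, no asym
    seq = "GAGAAACAC"  # pairs (1,9) G-C? check: G..C ; inner (3,7) G-C
    e = motif_energy("GAGAAACAC", 1, 3, 9, 7, params)
    assert e == (params.internal_init[2]) / 10
    # 2x0 bulge: initiation + end penalties (none for G-C/G-C)
    e = motif_energy("GAAGAAACC", 1, 4, 9, 8, params)
    assert e == params.bulge_init[2] / 10
    # oversized side is forbidden
    seq = "G" + "A" * 25 + "GAAAC" + "C"
    assert motif_energy(seq, 1, 27, len(seq), len(seq) - 1, params) == math.inf


def test_length_one_bulge_keeps_stack(params):
    # G-C over C-G with a single bulged A on the 5' side
    seq = "GACAAAGGC"  # pair (1,9) G-C, inner (3,8) C-G, bulge = position 2
    e = motif_energy(seq, 1, 3, 9, 8, params)
    assert e == (params.bulge_init[1] + params.stack_table[2, 1]) / 10


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_stack_equals_motif_property(seed):
    import random
    params = load_params()
    r = random.Random(seed)
    seq = "".join(r.choice("ACGU") for _ in range(r.randint(6, 30)))
    codes = encode(seq)
    n = len(seq)
    for m in range(1, n - 2):
        for p in range(m + 3, n + 1):
            s = stack_energy_t(codes, m, p, params)
            if s < INF:
                assert s == motif_energy_t(codes, m, m + 1, p, p - 1, params)


def test_energies_are_decimal_grid(params):
    # every table entry is an exact integer in tenths of kcal/mol
    for arr in (params.stack_table, params.hairpin_init,
                params.internal_init, params.bulge_init):
        assert arr.dtype.kind == "i"


def test_helix_hand_sum(params):
    # 5-pair helix GGGGG/CCCCC: 4 stack terms, hand-summed from the bundle
    seq = "GGGGGAAAACCCCC"
    codes = encode(seq)
    total = sum(stack_energy_t(codes, m, 15 - m, params) for m in range(1, 5))
    from costruct.thermo import PAIRS
    gc = list(PAIRS).index("GC")
    assert total == 4 * params.stack_table[gc, gc]


def test_bundle_round_trip(params, tmp_path):
    out = tmp_path / "bundle.txt"
    save_params(params, out)
    p2 = load_params(out)
    assert (p2.stack_table == params.stack_table).all()
    assert (p2.hairpin_init == params.hairpin_init).all()
    assert p2.gap_penalty == params.gap_penalty
    assert p2.min_hairpin == params.min_hairpin


def test_bundle_missing_table_is_error(params, tmp_path):
    out = tmp_path / "broken.txt"
    save_params(params, out)
    text = "\n".join(ln for ln in out.read_text().splitlines()
                     if not ln.startswith("hairpin"))
    out.write_text(text)
    with pytest.raises(BundleFormatError, match="hairpin"):
        load_params(out)
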