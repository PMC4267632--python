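"""Joint DP: band geometry, rescoring, traceback and end-to-end runs."""

import warnings

import pytest

from costruct import (CommonStructure, Domain, PredictConfig, StructureError,
                      fill, fold_single, filter_pairs, make_band, predict,
                      total_energy, traceback)
from costruct.core import default_band_width
from conftest import random_seq


def _prep(seq, params, window=1.0):
    t = fold_single(seq, params)
    filter_pairs(seq, t, window, params)
    return t


def test_band_membership():
    band = make_band(50, 50, 10)
    assert band.contains(25, 25)
    assert band.contains(25, 30)
    assert not band.contains(25, 31)
    assert band.contains(0, 0) and band.contains(50, 50)


def test_band_full_diagonal():
    band = make_band(40, 40, 2)
    assert all(band.contains(i, i) for i in range(41))


def test_band_widened_for_unequal_lengths():
    with pytest.warns(UserWarning, match="widened"):
        band = make_band(40, 60, 6)
    assert band.d == 40
    assert band.contains(40, 60)


def test_band_rejects_bad_lengths():
    with pytest.raises(ValueError):
        make_band(0, 10, 4)


def test_band_mirror_symmetry():
    band = make_band(30, 45, 12)
    for i in range(31):
        for k in range(46):
            assert band.contains(i, k) == band.contains(30 - i, 45 - k)


def test_identical_hairpins_no_gaps(params):
    seq = "GGGGAAAACCCC"
    t1 = _prep(seq, params)
    t2 = _prep(seq, params)
    band = make_band(12, 12, 24)
    for mode in ("original", "no_insert", "dynalign2"):
        tb = fill(seq, seq, t1, t2, band, params, mode)
        assert tb.opt_t == 2 * t1.mfe_t
        cs = traceback(tb)
        assert cs.pairs1 == cs.pairs2 == [(1, 12), (2, 11), (3, 10), (4, 9)]
        assert cs.n_gap == 0 and cs.domains == []


def test_mode_nesting_and_w5_w3(params, rng):
    for _ in range(6):
        s1 = random_seq(rng, rng.randint(7, 10))
        s2 = random_seq(rng, rng.randint(7, 10))
        t1, t2 = _prep(s1, params), _prep(s2, params)
        band = make_band(len(s1), len(s2), 2 * max(len(s1), len(s2)))
        es = {}
        for mode in ("original", "no_insert", "dynalign2"):
            tb = fill(s1, s2, t1, t2, band, params, mode)
            assert tb.opt_t == tb.w3_opt_t
            es[mode] = tb.opt_t
        assert es["dynalign2"] <= es["no_insert"] <= es["original"]


def test_band_monotonicity(params, rng):
    s1 = random_seq(rng, 20)
    s2 = random_seq(rng, 20)
    t1, t2 = _prep(s1, params), _prep(s2, params)
    prev = None
    for d in (4, 8, 16, 40):
        tb = fill(s1, s2, t1, t2, make_band(20, 20, d), params, "dynalign2")
        if prev is not None:
            assert tb.opt_t <= prev
        prev = tb.opt_t


def test_traceback_deterministic(params, rng):
    s1 = random_seq(rng, 10)
    s2 = random_seq(rng, 10)
    t1, t2 = _prep(s1, params), _prep(s2, params)
    band = make_band(10, 10, 20)
    tb = fill(s1, s2, t1, t2, band, params, "dynalign2")
    a = traceback(tb)
    b = traceback(tb)
    assert a.pairs1 == b.pairs1 and a.pairs2 == b.pairs2
    assert a.aligned == b.aligned


def test_total_energy_breakdown_consistency(params):
    seq = "GGGGAAAACCCC"
    cs = predict(seq, seq, PredictConfig(mode="dynalign2", band_width=24,
                                         window_percent=1.0))
    bd = cs.breakdown
    assert bd.total_t == (bd.dg1_t + bd.dg2_t + bd.gap_total_t
                          + bd.domain_total_t)
    assert bd.gap_total_t == bd.n_gap * params.gap_penalty


def test_total_energy_empty(params):
    cs = CommonStructure(pairs1=[], pairs2=[], aligned=[], domains=[])
    bd = total_energy(cs, "AAAAAA", "AAAAAA", params)
    assert bd.total_t == 0 and bd.n_gap == 0


def test_total_energy_domain_arithmetic(params):
    # adding one inserted domain of length x costs opening + x * elongation
    s1 = "GGGGGAAAACCCCC"
    s2 = "GGGGGAAAACCCCC" + "AA" + "GGGGAAAACCCC"
    pairs_core = [(i, 15 - i) for i in range(1, 6)]
    dom_pairs = [(16 + i, 29 - i) for i in range(1, 5)]
    cs = CommonStructure(
        pairs1=pairs_core, pairs2=sorted(pairs_core + dom_pairs),
        aligned=[(a, b, a, b) for (a, b) in pairs_core],
        domains=[Domain(host=2, start=17, end=28, context="exterior")])
    bd = total_energy(cs, s1, s2, params)
    cs0 = CommonStructure(pairs1=pairs_core, pairs2=pairs_core,
                          aligned=[(a, b, a, b) for (a, b) in pairs_core],
                          domains=[])
    bd0 = total_energy(cs0, s1, s1, params)
    dom_fold = bd.dg2_t - bd0.dg2_t  # the domain's own folding energy
    assert bd.domain_total_t == params.domain_opening + 12 * params.domain_elongation
    assert bd.total_t == bd0.total_t + dom_fold + bd.domain_total_t + \
        (bd.n_gap - bd0.n_gap) * params.gap_penalty


def test_total_energy_rejects_crossing(params):
    cs = CommonStructure(pairs1=[(1, 8), (4, 12)], pairs2=[], aligned=[],
                         domains=[])
    with pytest.raises(StructureError):
        total_energy(cs, "GGGGAAAACCCCCC", "AAAA", params)


def test_default_band_width():
    assert default_band_width(50, 50) == 10
    assert default_band_width(120, 100) == 24


def test_predict_composes(params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs = predict("GGGGAAAACCCC", "GGGAAAACCC",
                     PredictConfig(mode="dynalign2", window_percent=1.0))
    assert len(cs.aligned) >= 3
    assert cs.breakdown.total_t == total_energy(
        cs, "GGGGAAAACCCC", "GGGAAAACCC", params).total_t


def test_domain_insertion_inside_multibranch_loop(params):
    # two hairpin branches under a closing helix; the second homolog carries
    # an extra stem-loop between the branches
    hp_a = "GGCGC" + "AAAA" + "GCGCC"
    hp_b = "GCGGG" + "AACA" + "CCCGC"
    ins = "GGGCG" + "AAAA" + "CGCCC"
    s1 = "GGGGG" + "AC" + hp_a + "AA" + hp_b + "CA" + "CCCCC"
    s2 = "GGGGG" + "AC" + hp_a + "A" + ins + "A" + hp_b + "CA" + "CCCCC"
    t1, t2 = _prep(s1, params, 0.2), _prep(s2, params, 0.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        band = make_band(len(s1), len(s2), 40)
    tb = fill(s1, s2, t1, t2, band, params, "dynalign2")
    cs = traceback(tb)
    assert tb.opt_t == tb.w3_opt_t
    assert len(cs.domains) == 1
    assert cs.domains[0].host == 2 and cs.domains[0].context == "mbl"
    # the planted stem's pairs appear inside the recorded interval
    d = cs.domains[0]
    inside = [(a, b) for (a, b) in cs.pairs2 if d.start <= a and b <= d.end]
    assert len(inside) >= 4


def test_stem_extension_recovers_jitter_pair(params):
    from costruct.oracle import FixtureSpec, make_fixture
    s1, s2, ref, _aln = make_fixture(FixtureSpec(seed=41, mutation_rate=0.0,
                                                 helix_jitter=1))
    extra = sorted(set(ref.pairs2) - set(ref.pairs1))
    assert len(extra) == 1  # one extra pair extends stem 1 of sequence 2
    t1, t2 = _prep(s1, params, 0.2), _prep(s2, params, 0.2)
    band = make_band(len(s1), len(s2), 20)
    es = {}
    for mode in ("original", "no_insert"):
        tb = fill(s1, s2, t1, t2, band, params, mode)
        cs = traceback(tb)
        es[mode] = (tb.opt_t, set(cs.pairs2))
    # the stackII move set can keep the extra pair; both modes stay exact
    assert es["no_insert"][0] <= es["original"][0]
    assert extra[0] in es["no_insert"][1]
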