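"""Accuracy metrics: slip rule, pooling, domain restriction, paired test."""

import math

import pytest
from scipy import stats

from costruct import metrics
from costruct.metrics import PairCounts


@pytest.mark.parametrize("pred,known,flex_ok", [
    ((2, 9), {(2, 9)}, True),
    ((2, 9), {(2, 10)}, True),   # i-(j+1)
    ((2, 9), {(2, 8)}, True),    # i-(j-1)
    ((2, 9), {(1, 9)}, True),    # (i-1)-j
    ((2, 9), {(3, 9)}, True),    # (i+1)-j
    ((3, 9), {(2, 10)}, False),  # double slip not allowed
])
def test_slip_rule(pred, known, flex_ok):
    assert metrics.pair_matches(pred, known, strict=False) is flex_ok
    assert metrics.pair_matches(pred, known, strict=True) is (pred in known)


def test_score_pair_basic():
    known = [(1, 10), (2, 9)]
    sens, ppv, _ = metrics.score_pair(known, known, known, known)
    assert sens == 1.0 and ppv == 1.0
    sens, ppv, _ = metrics.score_pair([], [], known, known)
    assert sens == 0.0 and ppv is None
    sens, ppv, _ = metrics.score_pair([(1, 10), (3, 8)], [], known, [],
                                      strict=True)
    assert sens == 0.5 and ppv == 0.5


def test_flexible_never_below_strict(rng):
    for _ in range(50):
        n = 30
        known = {(rng.randint(1, 15), rng.randint(16, 30)) for _ in range(5)}
        pred = {(rng.randint(1, 15), rng.randint(16, 30)) for _ in range(5)}
        s_strict, p_strict, _ = metrics.score_pair(pred, [], known, [],
                                                   strict=True)
        s_flex, p_flex, _ = metrics.score_pair(pred, [], known, [],
                                               strict=False)
        assert s_flex >= s_strict and p_flex >= p_strict


def test_pool_family_ratio_of_sums():
    a = PairCounts(known=2, predicted=2, correct_of_known=1, correct_of_pred=1)
    b = PairCounts(known=3, predicted=3, correct_of_known=3, correct_of_pred=3)
    sens, ppv = metrics.pool_family([a, b])
    assert sens == 4 / 5 and ppv == 4 / 5
    assert metrics.pool_family([b, a]) == (sens, ppv)  # permutation invariant
    with pytest.raises(ValueError):
        metrics.pool_family([])


def test_find_inserted_domains():
    # seq2 has a 10-nt unaligned block [11, 20] holding a 3-pair stem
    cols = [(i, i) for i in range(1, 11)]
    cols += [(None, k) for k in range(11, 21)]
    cols += [(i, i + 10) for i in range(11, 21)]
    known2 = [(12, 19), (13, 18), (14, 17)]
    doms = metrics.find_inserted_domains([], known2, cols)
    assert doms == [(2, 11, 20)]
    # without a nested pair the block is not a domain
    assert metrics.find_inserted_domains([], [], cols) == []
    # a pair straddling the block boundary disqualifies nothing else
    assert metrics.find_inserted_domains([], [(5, 15)], cols) == []


def test_inserted_domain_accuracy_undefined_without_predictions():
    from costruct import CommonStructure
    known2 = [(12, 19), (13, 18)]
    cs = CommonStructure(pairs1=[], pairs2=[], aligned=[], domains=[])
    sens, ppv, _ = metrics.inserted_domain_accuracy(cs, [], known2,
                                                    [(2, 11, 20)])
    assert sens == 0.0 and ppv is None
    sens, ppv, _ = metrics.inserted_domain_accuracy(cs, [], [], [])
    assert sens is None and ppv is None


def test_paired_test_identical_inputs():
    assert metrics.paired_one_tailed_test([0.5, 0.6, 0.7],
                                          [0.5, 0.6, 0.7]) == 0.5


def test_paired_test_closed_form():
    a = [0.6, 0.7, 0.75, 0.9]
    b = [0.5, 0.55, 0.8, 0.7]
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    expect = float(stats.t.sf(t, df=n - 1))
    assert metrics.paired_one_tailed_test(a, b) == pytest.approx(expect)
    # constant positive differences: t -> infinity, p -> 0
    assert metrics.paired_one_tailed_test([0.6] * 4, [0.5] * 4) == 0.0


def test_paired_test_swap_symmetry():
    a = [0.6, 0.7, 0.75, 0.9]
    b = [0.5, 0.55, 0.8, 0.7]
    p_ab = metrics.paired_one_tailed_test(a, b)
    p_ba = metrics.paired_one_tailed_test(b, a)
    assert p_ab + p_ba == pytest.approx(1.0)


def test_paired_test_errors():
    with pytest.raises(ValueError):
        metrics.paired_one_tailed_test([0.1], [0.2])
    with pytest.raises(ValueError):
        metrics.paired_one_tailed_test([0.1, 0.2], [0.2])
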