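"""Structure-prediction accuracy: sensitivity, PPV, and significance.

Sensitivity is the fraction of known base pairs that are predicted; PPV
the fraction of predicted pairs that are known.  In flexible mode a pair
i-j also matches (i+1)-j, (i-1)-j, i-(j-1) or i-(j+1), tolerating
single-nucleotide slips of one pairing partner.  Family-level rates pool
counts (ratio of sums, never a mean of ratios).  Undefined rates (0/0)
are reported as None and excluded from pooled denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def pair_matches(pred, known, strict: bool = False) -> bool:
    """Does a predicted pair hit the known set, with optional slip?"""
    i, j = pred
    if (i, j) in known:
        return True
    if strict:
        return False
    return any(v in known for v in
               ((i + 1, j), (i - 1, j), (i, j - 1), (i, j + 1)))


@dataclass
class PairCounts:
    """Raw counts for one homolog pair (both sequences pooled)."""

    known: int = 0
    predicted: int = 0
    correct_of_known: int = 0   # known pairs that are predicted
    correct_of_pred: int = 0    # predicted pairs that are in the known set

    @property
    def sensitivity(self):
        return None if self.known == 0 else self.correct_of_known / self.known

    @property
    def ppv(self):
        return (None if self.predicted == 0
                else self.correct_of_pred / self.predicted)

    def __add__(self, other):
        return PairCounts(
            self.known + other.known, self.predicted + other.predicted,
            self.correct_of_known + other.correct_of_known,
            self.correct_of_pred + other.correct_of_pred)


def _count_one(pred, known, strict) -> PairCounts:
    pred = set(map(tuple, pred))
    known = set(map(tuple, known))
    c = PairCounts(known=len(known), predicted=len(pred))
    c.correct_of_known = sum(pair_matches(kp, pred, strict) for kp in known)
    c.correct_of_pred = sum(pair_matches(pp, known, strict) for pp in pred)
    return c


def score_pair(pred1, pred2, known1, known2, strict: bool = False):
    """Per-homolog-pair sensitivity and PPV, pooled over both sequences.

    Returns (sensitivity, ppv, PairCounts); undefined rates are None.
    """
    c = _count_one(pred1, known1, strict) + _count_one(pred2, known2, strict)
    return c.sensitivity, c.ppv, c


def pool_family(counts) -> tuple:
    """Family rates as ratios of summed counts, never means of ratios."""
    counts = list(counts)
    if not counts:
        raise ValueError("cannot pool an empty list of reports")
    tot = PairCounts()
    for c in counts:
        tot = tot + c
    return tot.sensitivity, tot.ppv


def find_inserted_domains(known1, known2, ref_alignment):
    """Inserted domains from a reference alignment: maximal unaligned
    intervals of one sequence holding at least one fully nested base pair.

    ``ref_alignment`` is a column list (i or None, k or None).  Returns
    (host, start, end) triples.
    """
    runs = {1: [], 2: []}
    cur = {1: None, 2: None}
    for (i, k) in ref_alignment:
        for host, mine, other in ((1, i, k), (2, k, i)):
            if mine is not None and other is None:
                if cur[host] is None:
                    cur[host] = [mine, mine]
                else:
                    cur[host][1] = mine
            elif mine is not None:
                if cur[host] is not None:
                    runs[host].append(tuple(cur[host]))
                    cur[host] = None
    for host in (1, 2):
        if cur[host] is not None:
            runs[host].append(tuple(cur[host]))
    out = []
    for host, pairs in ((1, known1), (2, known2)):
        for (a, b) in runs[host]:
            if any(a <= x and y <= b for (x, y) in pairs):
                out.append((host, a, b))
    return sorted(out)


def _pairs_in(pairs, start, end):
    return {(a, b) for (a, b) in pairs if start <= a and b <= end}


def inserted_domain_accuracy(pred_cs, known1, known2, domains,
                             strict: bool = False):
    """Accuracy restricted to inserted-domain base pairs.

    Sensitivity: known pairs inside reference inserted domains that are
    predicted.  PPV: predicted pairs inside predicted inserted-domain
    intervals that are in the known structure.  Undefined rates are None
    (for instance, a move set that cannot insert pairs predicts no
    domains, so its inserted-domain PPV cannot be calculated).
    """
    pred_sets = {1: set(map(tuple, pred_cs.pairs1)),
                 2: set(map(tuple, pred_cs.pairs2))}
    known_sets = {1: set(map(tuple, known1)), 2: set(map(tuple, known2))}
    c = PairCounts()
    for (host, a, b) in domains:
        kp = _pairs_in(known_sets[host], a, b)
        c.known += len(kp)
        c.correct_of_known += sum(
            pair_matches(p, pred_sets[host], strict) for p in kp)
    for d in pred_cs.domains:
        pp = _pairs_in(pred_sets[d.host], d.start, d.end)
        c.predicted += len(pp)
        c.correct_of_pred += sum(
            pair_matches(p, known_sets[d.host], strict) for p in pp)
    return c.sensitivity, c.ppv, c


def paired_one_tailed_test(acc_a, acc_b) -> float:
    """One-tailed paired t-test p-value for mean(a - b) > 0.

    Identical inputs (zero differences) give p = 0.5 by convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test needs equal-length accuracy lists")
    if len(a) < 2:
        raise ValueError("paired test needs at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.5
        return 0.0 if d.mean() > 0 else 1.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(stats.t.sf(t, df=len(d) - 1))


@dataclass
class EvalReport:
    """Per-pair and pooled accuracy, overall and domain-restricted."""

    per_pair: list = field(default_factory=list)  # PairCounts
    per_pair_domain: list = field(default_factory=list)
    p_value: float = None

    @property
    def pooled(self):
        return pool_family(self.per_pair)

    @property
    def pooled_domain(self):
        sens, ppv = None, None
        if self.per_pair_domain:
            sens, ppv = pool_family(self.per_pair_domain)
        return sens, ppv

    def as_dict(self):
        sens, ppv = self.pooled
        dsens, dppv = self.pooled_domain
        return {
            "n_pairs": len(self.per_pair),
            "sensitivity": sens, "ppv": ppv,
            "domain_sensitivity": dsens, "domain_ppv": dppv,
            "p_value": self.p_value,
        }
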