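"""Brute-force references and synthetic fixtures for validating the DP.

``enumerate_structures`` lists every pseudoknot-free structure of one short
sequence; ``enumerate_common`` exhausts pairs of structures, alignments and
insertion annotations for two short sequences and rescores each candidate
with :func:`costruct.core.total_energy`.  Neither shares any code with the
DP fill, so agreement between the two routes exercises the recursion design
end to end.

The fixture generator emulates homolog pairs sharing a conserved core:
hairpin modules separated by unpairable linkers (A/C alphabet outside
stems), compensatory mutations on conserved pairs, optional helix-length
jitter, and an optionally planted stem-loop domain inserted in one
sequence's linker.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .thermo import EnergyParams, encode, end_penalty_t
from .core import (CommonStructure, Domain, StructureError, _relation,
                   _single_energy, total_energy)
from .singlefold import fold_single, mfe_structure

_MAX_ENUM = 14
_MAX_COMMON = 10

_CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"),
          ("U", "G")}


def enumerate_structures(seq: str, params: EnergyParams):
    """All pseudoknot-free structures over canonical pairs (loops >=
    min_hairpin), each with its nearest-neighbor energy in tenths."""
    n = len(seq)
    if n > _MAX_ENUM:
        raise ValueError(f"sequence longer than enumeration guard {_MAX_ENUM}")
    minhp = params.min_hairpin
    codes = encode(seq)

    memo = {}

    def structs(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i + 1 < minhp + 2:
            return [()]
        out = list(structs(i + 1, j))
        for h in range(i + minhp + 1, j + 1):
            if (seq[i - 1], seq[h - 1]) in _CANON:
                for inner in structs(i + 1, h - 1):
                    for rest in structs(h + 1, j):
                        out.append(((i, h),) + inner + rest)
        memo[(i, j)] = out
        return out

    result = []
    for pairs in structs(1, n):
        pairs = tuple(sorted(pairs))
        result.append((pairs, _exterior_energy(codes, pairs, n, params)))
    return result


def _exterior_energy(codes, pairs, n, params):
    """Energy of a whole structure: sum of top-level branch energies plus
    their helix-end penalties (exterior unpaired nucleotides are free)."""
    pt = [0] * (n + 2)
    for (a, b) in pairs:
        pt[a] = b
        pt[b] = a
    e = 0
    x = 1
    while x <= n:
        if pt[x] > x:
            e += (_single_energy(codes, pt, x, pt[x], params)
                  + end_penalty_t(codes, x, pt[x], params))
            x = pt[x] + 1
        else:
            x += 1
    return e


def count_structures_recurrence(seq: str, params: EnergyParams) -> int:
    """Independent structure counter (interval recurrence, no listing)."""
    n = len(seq)
    minhp = params.min_hairpin
    memo = {}

    def cnt(i, j):
        if j - i + 1 < minhp + 2:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = cnt(i + 1, j)
        for h in range(i + minhp + 1, j + 1):
            if (seq[i - 1], seq[h - 1]) in _CANON:
                total += cnt(i + 1, h - 1) * cnt(h + 1, j)
        memo[(i, j)] = total
        return total

    return cnt(1, n)


# ---------------------------------------------------------------------------
# joint enumeration

def _matchings(pairs1, pairs2):
    """All partial bijections between the two pair lists that preserve the
    mutual arrangement (before/inside relations) on both sides."""
    p1 = sorted(pairs1)
    p2 = sorted(pairs2)

    def rec(idx, used2, acc):
        if idx == len(p1):
            yield tuple(acc)
            return
        yield from rec(idx + 1, used2, acc)  # p1[idx] unmatched
        a = p1[idx]
        for b in p2:
            if b in used2:
                continue
            ok = True
            for (x, y) in acc:
                if _relation(a, x) != _relation(b, y):
                    ok = False
                    break
            if ok:
                yield from rec(idx + 1, used2 | {b}, acc + [(a, b)])

    yield from rec(0, frozenset(), [])


def _closed_down(sel, allpairs):
    """True if every pair nested inside a selected pair is selected."""
    for p in sel:
        for q in allpairs:
            if q not in sel and p[0] < q[0] and q[1] < p[1]:
                return False
    return True


def _outermost(sel):
    out = []
    for p in sorted(sel):
        if not any(q[0] < p[0] and p[1] < q[1] for q in sel if q != p):
            out.append(p)
    return out


def _domain_interval_sets(host, dom_pairs, blocked, n, matched_spans):
    """Enumerate ways to cover ``dom_pairs`` (outermost ones disjoint) with
    disjoint intervals avoiding ``blocked`` positions."""
    tops = _outermost(dom_pairs)
    if not tops:
        yield []
        return
    # split points: partition consecutive tops into groups
    for cuts in itertools.product([0, 1], repeat=len(tops) - 1):
        groups = [[tops[0]]]
        for t, cut in zip(tops[1:], cuts):
            if cut:
                groups.append([t])
            else:
                groups[-1].append(t)
        # interval bounds per group
        choices = []
        feasible = True
        for g in groups:
            lo_min = max([b for b in blocked if b < g[0][0]], default=0) + 1
            hi_max = min([b for b in blocked if b > g[-1][1]],
                         default=n + 1) - 1
            if lo_min > g[0][0] or hi_max < g[-1][1]:
                feasible = False
                break
            opts = [(a, b)
                    for a in range(lo_min, g[0][0] + 1)
                    for b in range(g[-1][1], hi_max + 1)]
            choices.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*choices):
            ok = all(combo[t][1] < combo[t + 1][0]
                     for t in range(len(combo) - 1))
            ok = ok and not any(a <= bl <= b for (a, b) in combo
                                for bl in blocked)
            if not ok:
                continue
            doms = []
            for (a, b) in combo:
                encl = [s for s in matched_spans if s[0] < a and b < s[1]]
                ctx = "mbl" if encl else "exterior"
                doms.append(Domain(host=host, start=a, end=b, context=ctx))
            yield doms


def enumerate_common(seq1: str, seq2: str, params: EnergyParams,
                     mode: str = "dynalign2"):
    """Exhaustive optimum of the joint objective for two short sequences.

    Returns ``(CommonStructure, energy_tenths)`` for the best candidate.
    The move set follows ``mode``: ``original`` requires every base pair
    aligned; ``no_insert`` additionally allows unaligned helix-extension
    pairs; ``dynalign2`` also allows inserted domains.
    """
    if len(seq1) > _MAX_COMMON or len(seq2) > _MAX_COMMON:
        raise ValueError(f"sequences longer than guard {_MAX_COMMON}")
    n1, n2 = len(seq1), len(seq2)
    c1 = encode(seq1)
    c2 = encode(seq2)
    structs1 = enumerate_structures(seq1, params)
    structs2 = enumerate_structures(seq2, params)
    best = None
    best_cs = None
    for pairs1, _e1 in structs1:
        for pairs2, _e2 in structs2:
            for m in _matchings(pairs1, pairs2):
                if mode == "original" and (len(m) != len(pairs1)
                                           or len(m) != len(pairs2)):
                    continue
                un1 = [p for p in pairs1 if p not in {a for a, _ in m}]
                un2 = [p for p in pairs2 if p not in {b for _, b in m}]
                matched_spans1 = [a for a, _ in m]
                matched_spans2 = [b for _, b in m]
                quads = sorted((a[0], a[1], b[0], b[1]) for a, b in m)
                for sel1 in _subsets(un1):
                    if mode != "dynalign2" and sel1:
                        break
                    if not _closed_down(set(sel1), pairs1):
                        continue
                    for sel2 in _subsets(un2):
                        if mode != "dynalign2" and sel2:
                            break
                        if not _closed_down(set(sel2), pairs2):
                            continue
                        blocked1 = _blocked(matched_spans1,
                                            set(un1) - set(sel1))
                        blocked2 = _blocked(matched_spans2,
                                            set(un2) - set(sel2))
                        for d1 in _domain_interval_sets(
                                1, list(sel1), blocked1, n1, matched_spans1):
                            for d2 in _domain_interval_sets(
                                    2, list(sel2), blocked2, n2,
                                    matched_spans2):
                                cs = CommonStructure(
                                    pairs1=list(pairs1), pairs2=list(pairs2),
                                    aligned=quads, domains=d1 + d2)
                                try:
                                    bd = total_energy(cs, c1, c2, params)
                                except (StructureError, AssertionError):
                                    continue
                                if best is None or bd.total_t < best:
                                    best = bd.total_t
                                    cs.n_gap = bd.n_gap
                                    cs.breakdown = bd
                                    best_cs = cs
    return best_cs, best


def _subsets(items):
    for r in range(len(items) + 1):
        yield from itertools.combinations(items, r)


def _blocked(matched_spans, chain_pairs):
    """Positions a domain interval may not cover."""
    out = set()
    for (a, b) in matched_spans:
        out.add(a)
        out.add(b)
    for (a, b) in chain_pairs:
        out.add(a)
        out.add(b)
    return out


# ---------------------------------------------------------------------------
# fixtures

@dataclass
class FixtureSpec:
    """Recipe for a homolog pair with a conserved multi-hairpin core.

    ``insertion`` plants a stem-loop domain in one sequence's linker:
    (host, stem_pairs, loop_len).  ``mutation_rate`` applies compensatory
    substitutions per conserved pair; ``helix_jitter`` extends one core
    helix of sequence 2 by one pair (a stem extension).
    """

    seed: int
    n_stems: int = 3
    stem_len: int = 5
    loop_len: int = 4
    linker_len: int = 6
    mutation_rate: float = 0.3
    insertion: tuple = None  # (host, stem_pairs, loop_len)
    helix_jitter: int = 0

    def __post_init__(self):
        if self.n_stems < 1 or self.stem_len < 2:
            raise ValueError("fixture needs at least one stem of >= 2 pairs")
        if self.insertion is not None:
            host, stem, loop = self.insertion
            if host not in (1, 2) or stem < 2 or loop < 3:
                raise ValueError(f"unsatisfiable insertion spec {self.insertion}")


_STEM_PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


def _rand_loop(rng, n):
    return "".join(rng.choice("AC") for _ in range(n))


def _stemloop(rng, stem, loop, gc_only=False, loop_fill=None):
    """Sequence of a stem-loop plus its pair list (local 1-based)."""
    pool = [("G", "C"), ("C", "G")] if gc_only else _STEM_PAIRS
    left = []
    right = []
    for _ in range(stem):
        a, b = rng.choice(pool)
        left.append(a)
        right.append(b)
    mid = loop_fill * loop if loop_fill else _rand_loop(rng, loop)
    seq = "".join(left) + mid + "".join(reversed(right))
    pairs = [(t + 1, 2 * stem + loop - t) for t in range(stem)]
    return seq, pairs


def make_fixture(spec: FixtureSpec):
    """Generate (seq1, seq2, reference CommonStructure, reference alignment).

    The reference alignment is a list of columns (i or None, k or None);
    inserted-domain nucleotides are aligned to nothing.  Deterministic for
    a given spec.

    Self-check: the reference structure (conserved core, jitter pair and
    planted domain) must be the minimum-free-energy fold of each sequence
    under the shipped parameters, so the planted features are
    thermodynamically supported in context; failing draws are redrawn
    deterministically.
    """
    from .thermo import load_params
    pchk = load_params()
    last = None
    for attempt in range(60):
        rng = random.Random(f"{spec.seed}:{attempt}")
        seq1, seq2, ref, alignment = _build_fixture(rng, spec)
        t1 = fold_single(seq1, pchk)
        if sorted(mfe_structure(t1, pchk)) != ref.pairs1:
            last = "sequence 1 reference is not its MFE fold"
            continue
        t2 = fold_single(seq2, pchk)
        if sorted(mfe_structure(t2, pchk)) != ref.pairs2:
            last = "sequence 2 reference is not its MFE fold"
            continue
        return seq1, seq2, ref, alignment
    raise RuntimeError(
        f"could not generate a stable fixture for seed {spec.seed}: {last}")


def _build_fixture(rng, spec: FixtureSpec):
    parts = []
    pairs_core = []
    pos = 0
    stem_spans = []
    linker_spans = []

    def add(text):
        nonlocal pos
        parts.append(text)
        pos += len(text)

    add(_rand_loop(rng, spec.linker_len))
    linker_spans.append((pos - spec.linker_len + 1, pos))
    for si in range(spec.n_stems):
        # a jittered helix needs a loop that can give up two nucleotides
        # and still close a legal hairpin
        loop_len = spec.loop_len
        if spec.helix_jitter and si == 0:
            loop_len = max(loop_len, 5)
        seq_s, pl = _stemloop(rng, spec.stem_len, loop_len, gc_only=True)
        off = pos
        add(seq_s)
        pairs_core.extend([(a + off, b + off) for (a, b) in pl])
        stem_spans.append((off + 1, pos))
        add(_rand_loop(rng, spec.linker_len))
        linker_spans.append((pos - spec.linker_len + 1, pos))
    seq1 = "".join(parts)

    # sequence 2 core: compensatory mutations, optional helix jitter
    s2 = list(seq1)
    for (a, b) in pairs_core:
        if rng.random() < spec.mutation_rate:
            x, y = rng.choice(_STEM_PAIRS)
            s2[a - 1] = x
            s2[b - 1] = y
    jitter_pairs = []
    if spec.helix_jitter:
        (a0, b0) = stem_spans[0]
        inner_i = a0 + spec.stem_len
        inner_j = b0 - spec.stem_len
        if inner_j - inner_i - 1 >= 3:
            s2[inner_i - 1] = "G"
            s2[inner_j - 1] = "C"
            jitter_pairs.append((inner_i, inner_j))
    seq2 = "".join(s2)

    pairs1 = sorted(pairs_core)
    pairs2 = sorted(pairs_core)
    domains = []
    extra2 = list(jitter_pairs)

    if spec.insertion is not None:
        host, stem, loop = spec.insertion
        lo, hi = linker_spans[len(linker_spans) // 2]
        site = (lo + hi) // 2  # insert after this position

        ins_seq, ins_pl = _stemloop(rng, stem, loop, gc_only=True,
                                    loop_fill="A")
        ins_len = len(ins_seq)

        def shift(pairs):
            return sorted((a + (ins_len if a > site else 0),
                           b + (ins_len if b > site else 0))
                          for (a, b) in pairs)

        dom_pairs = sorted((a + site, b + site) for (a, b) in ins_pl)
        dom = Domain(host=host, start=site + 1, end=site + ins_len,
                     context="exterior")
        domains.append(dom)
        if host == 1:
            seq1 = seq1[:site] + ins_seq + seq1[site:]
            pairs1 = sorted(shift(pairs1) + dom_pairs)
        else:
            seq2 = seq2[:site] + ins_seq + seq2[site:]
            pairs2 = shift(pairs2)
            extra2 = shift(extra2)
            pairs2 = sorted(pairs2 + dom_pairs)

    conserved1 = sorted(set(pairs1) - _interval_pairs(pairs1, domains, 1))
    pairs2 = sorted(set(pairs2) | set(extra2))
    conserved2 = sorted(set(pairs2) - set(extra2)
                        - _interval_pairs(pairs2, domains, 2))
    aligned = [(p1[0], p1[1], p2[0], p2[1])
               for p1, p2 in zip(conserved1, conserved2)]
    ref = CommonStructure(pairs1=pairs1, pairs2=pairs2,
                          aligned=sorted(aligned), domains=domains)
    alignment = _reference_alignment(len(seq1), len(seq2), domains)
    return seq1, seq2, ref, alignment


def _interval_pairs(pairs, domains, host):
    out = set()
    for d in domains:
        if d.host == host:
            out |= {(a, b) for (a, b) in pairs
                    if d.start <= a and b <= d.end}
    return out


def _reference_alignment(n1, n2, domains):
    """Column list (i or None, k or None) aligning the two sequences."""
    cols = []
    if not domains:
        for x in range(1, min(n1, n2) + 1):
            cols.append((x, x))
        return cols
    d = domains[0]
    if d.host == 1:
        i = k = 1
        for x in range(1, n1 + 1):
            if d.start <= x <= d.end:
                cols.append((x, None))
            else:
                cols.append((x, k))
                k += 1
    else:
        k_in_2 = 1
        i = 1
        for y in range(1, n2 + 1):
            if d.start <= y <= d.end:
                cols.append((None, y))
            else:
                cols.append((i, y))
                i += 1
    return cols
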