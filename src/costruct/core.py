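"""Joint fold-and-align of two RNA homologs by free-energy minimization.

The optimization target is the total free energy

    dG_total = dG1 + dG2 + n_gap * gap_penalty
               + sum_i (domain_opening + x_i * domain_elongation)

over all pseudoknot-free common structures and consistent alignments, where
dG1/dG2 are nearest-neighbor folding energies of the two structures, n_gap
counts unaligned nucleotides outside inserted domains, and each inserted
domain of length x_i pays an affine opening + elongation penalty instead of
per-gap penalties.

Three run modes nest their move sets:

* ``original``  -- conserved motifs only (every base pair aligned);
* ``no_insert`` -- adds stem extensions and internal loops aligned to
  stacked pairs ("stackII" moves), but no inserted domains;
* ``dynalign2`` -- additionally allows inserted folding domains, priced
  through precomputed single-sequence arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .thermo import (INF, EnergyParams, encode, load_params, motif_energy_t)
from .singlefold import (SingleFoldTables, _tables, fold_single, filter_pairs,
                         trace_wm, trace_web)
from ._fill import fill_kernel

MODES = ("dynalign2", "no_insert", "original")


class StructureError(ValueError):
    """A CommonStructure violates a structural invariant."""


# ---------------------------------------------------------------------------
# alignment band

@dataclass(frozen=True)
class AlignmentBand:
    """Diagonal band restricting aligned positions: |k - i*N2/N1| <= d/2."""

    n1: int
    n2: int
    d: int
    klo: np.ndarray
    khi: np.ndarray
    kw: int

    def contains(self, i: int, k: int) -> bool:
        if not (0 <= i <= self.n1 and 0 <= k <= self.n2):
            return False
        return self.klo[i] <= k <= self.khi[i]


def make_band(n1: int, n2: int, d: int) -> AlignmentBand:
    """Build the band; widens d (with a warning) so both endpoints of the
    alignment remain reachable (d >= 2|N1 - N2|)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sequence lengths must be positive")
    d = int(d)
    if d % 2:
        d += 1
    dmin = 2 * abs(n1 - n2)
    if d < dmin:
        warnings.warn(
            f"band width {d} too narrow for lengths {n1},{n2}; widened to {dmin}")
        d = dmin
    if d < 2:
        d = 2
    klo = np.zeros(n1 + 2, dtype=np.int32)
    khi = np.zeros(n1 + 2, dtype=np.int32)
    for i in range(n1 + 1):
        # |2*k*n1 - 2*i*n2| <= d*n1
        klo[i] = max(0, -((-(2 * i * n2 - d * n1)) // (2 * n1)))
        khi[i] = min(n2, (2 * i * n2 + d * n1) // (2 * n1))
    klo[n1 + 1] = n2 + 1
    khi[n1 + 1] = n2
    kw = int(max(khi[: n1 + 1] - klo[: n1 + 1])) + 1
    return AlignmentBand(n1=n1, n2=n2, d=d, klo=klo, khi=khi, kw=kw)


def default_band_width(n1: int, n2: int) -> int:
    d = max(10, math.ceil(0.2 * max(n1, n2)))
    return d + (d % 2)


# ---------------------------------------------------------------------------
# result containers

@dataclass
class Domain:
    """An inserted folding domain: interval [start, end] of one sequence.

    ``context`` records whether the insertion sits in a multibranch loop
    ("mbl") or in the exterior loop ("exterior"); the two contexts price
    unpaired nucleotides differently, mirroring the single-sequence arrays
    used to fill them.
    """

    host: int  # 1 or 2
    start: int
    end: int
    context: str  # "mbl" | "exterior"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EnergyBreakdown:
    dg1_t: int
    dg2_t: int
    n_gap: int
    gap_total_t: int
    domain_total_t: int
    total_t: int

    @property
    def dg1(self):
        return self.dg1_t / 10.0

    @property
    def dg2(self):
        return self.dg2_t / 10.0

    @property
    def gap_total(self):
        return self.gap_total_t / 10.0

    @property
    def domain_total(self):
        return self.domain_total_t / 10.0

    @property
    def total(self):
        return self.total_t / 10.0


@dataclass
class CommonStructure:
    """A common secondary structure for two homologs plus its alignment.

    ``aligned`` holds the conserved quadruples (i, j, k, l): pair i-j of
    sequence 1 aligned to pair k-l of sequence 2.  Pairs absent from
    ``aligned`` are either helix-extension pairs (on the descent path
    between two conserved pairs) or lie inside an inserted domain.
    """

    pairs1: list
    pairs2: list
    aligned: list
    domains: list
    n_gap: int = 0
    breakdown: EnergyBreakdown = None

    @property
    def alignment_pairs(self):
        """Aligned position pairs (i, k), restricted to conserved pairs."""
        out = []
        for (i, j, k, l) in sorted(self.aligned):
            out.append((i, k))
            out.append((j, l))
        return sorted(set(out))

    def conserved1(self):
        return {(i, j) for (i, j, _, _) in self.aligned}

    def conserved2(self):
        return {(k, l) for (_, _, k, l) in self.aligned}

    def domain_pairs(self, host: int):
        pairs = self.pairs1 if host == 1 else self.pairs2
        out = set()
        for d in self.domains:
            if d.host == host:
                out |= {(a, b) for (a, b) in pairs if d.start <= a and b <= d.end}
        return out


# ---------------------------------------------------------------------------
# independent rescoring (no DP tables involved)

def _partner(pairs, n, label):
    pt = [0] * (n + 2)
    for (a, b) in pairs:
        if not (1 <= a < b <= n):
            raise StructureError(f"{label}: pair {(a, b)} out of range")
        if pt[a] or pt[b]:
            raise StructureError(f"{label}: nucleotide in two pairs at {(a, b)}")
        pt[a] = b
        pt[b] = a
    stack = []
    for x in range(1, n + 1):
        if pt[x] > x:
            stack.append(pt[x])
        elif pt[x] and pt[x] < x:
            if not stack or stack[-1] != x:
                raise StructureError(f"{label}: crossing pair at {x}")
            stack.pop()
    return pt


def _single_energy(seq, pt, i, j, params: EnergyParams):
    """Nearest-neighbor energy (tenths) of the substructure rooted at pair
    (i, j) of one sequence, by standard loop decomposition."""
    from .thermo import hairpin_energy_t, end_penalty_t
    kids = []
    x = i + 1
    while x < j:
        if pt[x] > x:
            kids.append((x, pt[x]))
            x = pt[x] + 1
        else:
            x += 1
    if not kids:
        e = hairpin_energy_t(seq, i, j, params)
        if e >= INF:
            raise StructureError(f"hairpin loop too short at {(i, j)}")
        return e
    if len(kids) == 1:
        (a, b) = kids[0]
        m = motif_energy_t(seq, i, a, j, b, params)
        if m >= INF:
            raise StructureError(f"loop sides exceed cap at {(i, j)}-{(a, b)}")
        return m + _single_energy(seq, pt, a, b, params)
    e = (params.mbl_closure + params.mbl_branch
         + end_penalty_t(seq, i, j, params))
    unpaired = (j - i - 1) - sum(b - a + 1 for (a, b) in kids)
    e += params.mbl_unpaired * unpaired
    for (a, b) in kids:
        e += (params.mbl_branch + end_penalty_t(seq, a, b, params)
              + _single_energy(seq, pt, a, b, params))
    return e


def _domain_content(seq, pt, dom: Domain, params: EnergyParams):
    """Energy (tenths) of the structure inside a domain interval, priced as
    multibranch-loop content ("mbl") or exterior-loop content ("exterior")."""
    from .thermo import end_penalty_t
    e = 0
    covered = 0
    x = dom.start
    nbranch = 0
    while x <= dom.end:
        if pt[x] > x:
            if pt[x] > dom.end:
                raise StructureError(
                    f"pair {(x, pt[x])} straddles domain {dom}")
            e += _single_energy(seq, pt, x, pt[x], params)
            e += end_penalty_t(seq, x, pt[x], params)
            if dom.context == "mbl":
                e += params.mbl_branch
            covered += pt[x] - x + 1
            nbranch += 1
            x = pt[x] + 1
        else:
            x += 1
    if nbranch == 0:
        raise StructureError(f"domain {dom} contains no base pair")
    if dom.context == "mbl":
        e += params.mbl_unpaired * (dom.length - covered)
    return e


def _chain_min_gaps(chain1, chain2, params: EnergyParams):
    """Minimum number of gap nucleotides to descend through two chains of
    nested pairs, one per sequence, using the allowed motif-alignment steps.

    ``chain1``/``chain2`` start with the outer (already aligned) closing
    pair and proceed inward; both must be fully consumed.  Returns the gap
    count, or raises if no legal step decomposition exists.
    """
    cap = params.max_internal_side
    maxext = params.max_stackII_extension

    def sides_ok(outer, inner):
        a = inner[0] - outer[0]
        b = outer[1] - inner[1]
        return a >= 1 and b >= 1 and a - 1 <= cap and b - 1 <= cap, a, b

    memo = {}

    def go(u1, u2):
        if (u1, u2) in memo:
            return memo[(u1, u2)]
        if u1 == len(chain1) - 1 and u2 == len(chain2) - 1:
            return 0
        best = INF
        c1 = chain1[u1]
        c2 = chain2[u2]
        if u1 + 1 < len(chain1) and u2 + 1 < len(chain2):
            ok1, a, b = sides_ok(c1, chain1[u1 + 1])
            ok2, c, d = sides_ok(c2, chain2[u2 + 1])
            if ok1 and ok2:
                e = abs(a - c) + abs(b - d) + go(u1 + 1, u2 + 1)
                best = min(best, e)
        if u2 + 1 < len(chain2):
            ok2, c, d = sides_ok(c2, chain2[u2 + 1])
            if ok2:
                best = min(best, c + d + go(u1, u2 + 1))
        if u1 + 1 < len(chain1):
            ok1, a, b = sides_ok(c1, chain1[u1 + 1])
            if ok1:
                best = min(best, a + b + go(u1 + 1, u2))
        # lockstep stem extension: one motif in one sequence aligned with
        # dd consecutive stacked pairs in the other, no gaps
        for dd in range(2, maxext + 1):
            if u1 + 1 < len(chain1) and u2 + dd < len(chain2):
                n1 = chain1[u1 + 1]
                if n1[0] - c1[0] == dd and c1[1] - n1[1] == dd:
                    if all(chain2[u2 + t] == (c2[0] + t, c2[1] - t)
                           for t in range(1, dd + 1)):
                        best = min(best, go(u1 + 1, u2 + dd))
            if u2 + 1 < len(chain2) and u1 + dd < len(chain1):
                n2 = chain2[u2 + 1]
                if n2[0] - c2[0] == dd and c2[1] - n2[1] == dd:
                    if all(chain1[u1 + t] == (c1[0] + t, c1[1] - t)
                           for t in range(1, dd + 1)):
                        best = min(best, go(u1 + dd, u2 + 1))
        memo[(u1, u2)] = best
        return best

    g = go(0, 0)
    if g >= INF:
        raise StructureError("no legal motif-step decomposition for chains")
    return g


def _chain_motif_sum(seq, chain, params):
    """Sum of consecutive-pair motif energies along one chain (tenths)."""
    e = 0
    for outer, inner in zip(chain, chain[1:]):
        m = motif_energy_t(seq, outer[0], inner[0], outer[1], inner[1], params)
        if m >= INF:
            raise StructureError(
                f"chain motif {outer}->{inner} exceeds loop-size cap")
        e += m
    return e


def total_energy(cs: CommonStructure, seq1, seq2,
                 params: EnergyParams) -> EnergyBreakdown:
    """Rescore a CommonStructure from scratch (independent of DP tables).

    Decomposes both structures jointly: conserved quadruples define the
    shared tree; a loop is priced as a multibranch loop in both sequences
    whenever the two sequences disagree on branch count or an inserted
    domain is present (a lone stem loop aligned to a multibranch loop is
    then charged as a branch of a multibranch loop).  Gap counts are the
    per-region alignment-length differences, with inserted-domain
    nucleotides excluded.
    """
    from .thermo import hairpin_energy_t, end_penalty_t
    s1 = seq1 if isinstance(seq1, np.ndarray) else encode(seq1)
    s2 = seq2 if isinstance(seq2, np.ndarray) else encode(seq2)
    n1 = len(s1) - 1
    n2 = len(s2) - 1
    pt1 = _partner(cs.pairs1, n1, "structure 1")
    pt2 = _partner(cs.pairs2, n2, "structure 2")

    quads = sorted(cs.aligned)
    p1set = set(map(tuple, cs.pairs1))
    p2set = set(map(tuple, cs.pairs2))
    for (i, j, k, l) in quads:
        if (i, j) not in p1set or (k, l) not in p2set:
            raise StructureError(f"aligned quadruple {(i, j, k, l)} not paired")
    spans1 = [(i, j) for (i, j, _, _) in quads]
    spans2 = [(k, l) for (_, _, k, l) in quads]
    if len(set(spans1)) != len(spans1) or len(set(spans2)) != len(spans2):
        raise StructureError("a pair appears in two aligned quadruples")
    q_by1 = {(i, j): (k, l) for (i, j, k, l) in quads}
    # order/nesting isomorphism of the two sides
    for (a1, b1) in spans1:
        for (a2, b2) in spans1:
            r1 = _relation((a1, b1), (a2, b2))
            r2 = _relation(q_by1[(a1, b1)], q_by1[(a2, b2)])
            if r1 != r2:
                raise StructureError(
                    "aligned quadruples are not nesting-isomorphic")

    dom_pairs1 = cs.domain_pairs(1)
    dom_pairs2 = cs.domain_pairs(2)
    for d in cs.domains:
        pset = p1set if d.host == 1 else p2set
        if not any(d.start <= a and b <= d.end for (a, b) in pset):
            raise StructureError(f"domain {d} contains no base pair")
        qs = spans1 if d.host == 1 else spans2
        if any(d.start <= a <= d.end or d.start <= b <= d.end
               for (a, b) in qs):
            raise StructureError(f"domain {d} overlaps a conserved pair")

    left1 = sorted(p1set - set(spans1) - dom_pairs1)
    left2 = sorted(p2set - set(spans2) - dom_pairs2)

    root1 = (0, n1 + 1)
    root2 = (0, n2 + 1)
    gapq = params.gap_penalty

    dg = {1: 0, 2: 0}  # folding energy per sequence, tenths
    ngap = 0
    dom_total = 0

    def enclosing_quad(span, host):
        """Deepest aligned quadruple strictly containing span on host side."""
        cands = []
        for (i, j, k, l) in quads:
            s = (i, j) if host == 1 else (k, l)
            if s[0] < span[0] and span[1] < s[1]:
                cands.append((i, j, k, l))
        if not cands:
            return None
        return max(cands, key=lambda q: (q[0] if host == 1 else q[2]))

    # map loops: owner quadruple (or None for exterior) -> members
    node_children = {}
    for q in quads:
        parent = enclosing_quad((q[0], q[1]), 1)
        node_children.setdefault(parent, []).append(q)
    node_domains = {}
    for d in cs.domains:
        span = (d.start, d.end)
        parent = enclosing_quad(span, d.host)
        node_domains.setdefault(parent, []).append(d)
    node_chain = {1: {}, 2: {}}
    for host, leftovers in ((1, left1), (2, left2)):
        for p in leftovers:
            parent = enclosing_quad(p, host)
            if parent is None:
                raise StructureError(
                    f"unaligned pair {p} in the exterior loop (sequence {host})")
            node_chain[host].setdefault(parent, []).append(p)

    def region_gaps(open1, close1, open2, close2, kids, doms):
        """Gap count for the unpaired regions of one loop, both sequences."""
        anchors1 = [open1] + [(q[0], q[1]) for q in kids] + [(close1, close1)]
        anchors2 = [open2] + [(q[2], q[3]) for q in kids] + [(close2, close2)]
        total = 0
        for t in range(len(anchors1) - 1):
            lo1, hi1 = anchors1[t][1] + 1, anchors1[t + 1][0] - 1
            lo2, hi2 = anchors2[t][1] + 1, anchors2[t + 1][0] - 1
            r1 = max(0, hi1 - lo1 + 1)
            r2 = max(0, hi2 - lo2 + 1)
            for d in doms:
                lo, hi = (lo1, hi1) if d.host == 1 else (lo2, hi2)
                if lo <= d.start and d.end <= hi:
                    if d.host == 1:
                        r1 -= d.length
                    else:
                        r2 -= d.length
                elif not (d.end < lo or d.start > hi):
                    raise StructureError(
                        f"domain {d} straddles a loop region boundary")
            total += abs(r1 - r2)
        return total

    def do_node(q):
        nonlocal ngap, dom_total
        kids = sorted(node_children.get(q, []))
        doms = node_domains.get(q, [])
        if q is None:
            if doms and any(d.context != "exterior" for d in doms):
                raise StructureError("exterior domain with mbl context")
            for d in doms:
                dom_total += params.domain_opening + d.length * params.domain_elongation
                seq, pt = (s1, pt1) if d.host == 1 else (s2, pt2)
                dg[d.host] += _domain_content(seq, pt, d, params)
            for (i, j, k, l) in kids:
                dg[1] += end_penalty_t(s1, i, j, params)
                dg[2] += end_penalty_t(s2, k, l, params)
            ngap += region_gaps((0, 0), n1 + 1, (0, 0), n2 + 1, kids, doms)
            return
        (i, j, k, l) = q
        chain1 = [(i, j)] + sorted(node_chain[1].get(q, []))
        chain2 = [(k, l)] + sorted(node_chain[2].get(q, []))
        # validate chains: nested, enclosing all children and domains
        for host, ch in ((1, chain1), (2, chain2)):
            for a, b in zip(ch, ch[1:]):
                if not (a[0] < b[0] and b[1] < a[1]):
                    raise StructureError(f"chain pairs not nested at {a}, {b}")
            inner = ch[-1]
            for kid in kids:
                s = (kid[0], kid[1]) if host == 1 else (kid[2], kid[3])
                if not (inner[0] < s[0] and s[1] < inner[1]):
                    raise StructureError(
                        f"chain pair {inner} does not enclose child {s}")
            for d in doms:
                if d.host == host and not (inner[0] < d.start
                                           and d.end < inner[1]):
                    raise StructureError(
                        f"chain pair {inner} does not enclose domain {d}")
        e1 = chain1[-1]
        e2 = chain2[-1]
        if kids and len(kids) == 1 and not doms:
            # single conserved child: descend through chains onto the child
            kid = kids[0]
            full1 = chain1 + [(kid[0], kid[1])]
            full2 = chain2 + [(kid[2], kid[3])]
            ngap += _chain_min_gaps(full1, full2, params)
            dg[1] += _chain_motif_sum(s1, full1, params)
            dg[2] += _chain_motif_sum(s2, full2, params)
            return
        ngap += _chain_min_gaps(chain1, chain2, params)
        dg[1] += _chain_motif_sum(s1, chain1, params)
        dg[2] += _chain_motif_sum(s2, chain2, params)
        if not kids:
            if doms:
                raise StructureError(
                    "inserted domain in a loop without a conserved branch")
            h1 = hairpin_energy_t(s1, e1[0], e1[1], params)
            h2 = hairpin_energy_t(s2, e2[0], e2[1], params)
            if h1 >= INF or h2 >= INF:
                raise StructureError("hairpin loop below minimum size")
            dg[1] += h1
            dg[2] += h2
            ngap += abs((e1[1] - e1[0]) - (e2[1] - e2[0]))
            return
        # multibranch loop in both sequences
        for host, e, seq in ((1, e1, s1), (2, e2, s2)):
            dg[host] += (params.mbl_closure + params.mbl_branch
                         + end_penalty_t(seq, e[0], e[1], params))
        for kid in kids:
            dg[1] += params.mbl_branch + end_penalty_t(s1, kid[0], kid[1], params)
            dg[2] += params.mbl_branch + end_penalty_t(s2, kid[2], kid[3], params)
        covered1 = sum(kid[1] - kid[0] + 1 for kid in kids)
        covered2 = sum(kid[3] - kid[2] + 1 for kid in kids)
        dlen1 = sum(d.length for d in doms if d.host == 1)
        dlen2 = sum(d.length for d in doms if d.host == 2)
        u1 = (e1[1] - e1[0] - 1) - covered1 - dlen1
        u2 = (e2[1] - e2[0] - 1) - covered2 - dlen2
        if u1 < 0 or u2 < 0:
            raise StructureError("overlapping loop members")
        dg[1] += params.mbl_unpaired * u1
        dg[2] += params.mbl_unpaired * u2
        for d in doms:
            if d.context != "mbl":
                raise StructureError("interior domain must have mbl context")
            dom_total += params.domain_opening + d.length * params.domain_elongation
            seq, pt = (s1, pt1) if d.host == 1 else (s2, pt2)
            dg[d.host] += _domain_content(seq, pt, d, params)
        ngap += region_gaps((e1[0], e1[0]), e1[1], (e2[0], e2[0]), e2[1],
                            kids, doms)

    # walk: exterior first, then every quadruple (the walk prices each
    # loop exactly once; nested content is priced at the nested nodes)
    do_node(None)
    for q in quads:
        do_node(q)

    total = (dg[1] + dg[2] + ngap * gapq + dom_total)
    return EnergyBreakdown(
        dg1_t=dg[1], dg2_t=dg[2], n_gap=ngap, gap_total_t=ngap * gapq,
        domain_total_t=dom_total, total_t=total)


def _relation(a, b):
    if a == b:
        return "same"
    if a[0] < b[0] and b[1] < a[1]:
        return "contains"
    if b[0] < a[0] and a[1] < b[1]:
        return "inside"
    if a[1] < b[0]:
        return "before"
    if b[1] < a[0]:
        return "after"
    return "crossing"


# ---------------------------------------------------------------------------
# the joint DP: fill, traceback, end-to-end prediction

@dataclass
class DPTables:
    """Filled joint DP arrays plus everything traceback needs."""

    s1: np.ndarray
    s2: np.ndarray
    n1: int
    n2: int
    band: AlignmentBand
    params: EnergyParams
    mode: str
    V: np.ndarray
    W: np.ndarray
    w5_arr: np.ndarray
    w3_arr: np.ndarray
    singles1: SingleFoldTables
    singles2: SingleFoldTables
    allowed1: np.ndarray
    allowed2: np.ndarray
    stack4: np.ndarray
    hp: np.ndarray
    pen4: np.ndarray

    @property
    def use_stackii(self):
        return self.mode in ("no_insert", "dynalign2")

    @property
    def use_domain(self):
        return self.mode == "dynalign2"

    @property
    def opt_t(self) -> int:
        return int(self.w5_arr[self.n1, self.n2])

    @property
    def opt(self) -> float:
        return self.opt_t / 10.0

    @property
    def w3_opt_t(self) -> int:
        return int(self.w3_arr[1, 1])

    def get_v(self, i, j, k, l) -> int:
        b = self.band
        if not (1 <= i <= j <= self.n1 and 1 <= k <= l <= self.n2):
            return INF
        if k < b.klo[i] or k > b.khi[i] or l < b.klo[j] or l > b.khi[j]:
            return INF
        return int(self.V[i, j, k - b.klo[i], l - b.klo[j]])

    def get_w(self, i, j, k, l) -> int:
        b = self.band
        if not (1 <= i <= j <= self.n1 and 1 <= k <= l <= self.n2):
            return INF
        if k < b.klo[i] or k > b.khi[i] or l < b.klo[j] or l > b.khi[j]:
            return INF
        return int(self.W[i, j, k - b.klo[i], l - b.klo[j]])

    def motif1(self, m, n, p, q) -> int:
        return motif_energy_t(self.s1, m, n, p, q, self.params)

    def motif2(self, m, n, p, q) -> int:
        return motif_energy_t(self.s2, m, n, p, q, self.params)


def _pairin(allowed, n):
    """pairin[i, j]: some allowed pair lies entirely within [i, j]."""
    pin = np.zeros((n + 2, n + 2), dtype=np.bool_)
    for i in range(n, 0, -1):
        for j in range(i + 1, n + 1):
            pin[i, j] = allowed[i, j] or pin[i + 1, j] or pin[i, j - 1]
    return pin


def fill(seq1, seq2, singles1: SingleFoldTables, singles2: SingleFoldTables,
         band: AlignmentBand, params: EnergyParams,
         mode: str = "dynalign2") -> DPTables:
    """Fill V, W, W5 and W3 for the selected move set (smaller fragments
    first).  ``singles1``/``singles2`` must come from :func:`fold_single`
    on the same sequences with the same parameters."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    s1, s2 = singles1.seq, singles2.seq
    n1, n2 = singles1.n, singles2.n
    if band.n1 != n1 or band.n2 != n2:
        raise ValueError("band does not match sequence lengths")
    if band.kw < 1:
        raise ValueError("degenerate alignment band")
    stack4, hp, il, bl, pen4, can = _tables(params, max(n1, n2))
    use_stackii = mode in ("no_insert", "dynalign2")
    use_domain = mode == "dynalign2"
    V, W, W5, W3 = fill_kernel(
        s1, s2, n1, n2, band.klo, band.khi, band.kw,
        singles1.allowed, singles2.allowed,
        _pairin(singles1.allowed, n1), _pairin(singles2.allowed, n2),
        singles1.wm, singles2.wm, singles1.web, singles2.web,
        stack4, hp, il, bl, pen4, can,
        params.internal_asymmetry, params.internal_asymmetry_cap,
        params.max_internal_side, params.max_stackII_extension,
        params.min_hairpin,
        params.mbl_closure, params.mbl_branch, params.mbl_unpaired,
        params.gap_penalty, params.domain_opening, params.domain_elongation,
        use_stackii, use_domain)
    return DPTables(
        s1=s1, s2=s2, n1=n1, n2=n2, band=band, params=params, mode=mode,
        V=V, W=W, w5_arr=W5, w3_arr=W3, singles1=singles1, singles2=singles2,
        allowed1=singles1.allowed, allowed2=singles2.allowed,
        stack4=stack4, hp=hp, pen4=pen4)


def traceback(tables: DPTables) -> CommonStructure:
    """Trace the optimal common structure and verify it by rescoring.

    The returned structure's independent rescoring equals W5(N1, N2)
    exactly; a mismatch raises AssertionError.
    """
    from ._trace import run_traceback
    tr = run_traceback(tables)
    cs = CommonStructure(
        pairs1=sorted(tr.pairs1), pairs2=sorted(tr.pairs2),
        aligned=sorted(tr.aligned), domains=tr.domains)
    bd = total_energy(cs, tables.s1, tables.s2, tables.params)
    assert bd.total_t == tables.opt_t, (
        f"rescoring mismatch: {bd.total_t} != W5 {tables.opt_t}")
    cs.n_gap = bd.n_gap
    cs.breakdown = bd
    return cs


@dataclass
class PredictConfig:
    mode: str = "dynalign2"
    band_width: int = None
    window_percent: float = 0.2
    params: EnergyParams = None


def predict(seq1: str, seq2: str, config: PredictConfig = None,
            **kwargs) -> CommonStructure:
    """End-to-end prediction: single-sequence folds, pair filter, band,
    joint fill and traceback."""
    cfg = config or PredictConfig(**kwargs)
    params = cfg.params or load_params()
    t1 = fold_single(seq1, params)
    t2 = fold_single(seq2, params)
    filter_pairs(seq1, t1, cfg.window_percent, params)
    filter_pairs(seq2, t2, cfg.window_percent, params)
    d = cfg.band_width or default_band_width(t1.n, t2.n)
    band = make_band(t1.n, t2.n, d)
    tables = fill(seq1, seq2, t1, t2, band, params, cfg.mode)
    assert tables.opt_t == tables.w3_opt_t, (
        f"W5/W3 mismatch: {tables.opt_t} != {tables.w3_opt_t}")
    return traceback(tables)
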