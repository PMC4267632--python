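"""Single-sequence free-energy minimization (Zuker-style) and pair filtering.

Produces, besides the minimum free energy, the auxiliary arrays consumed by
the joint fold-and-align program when it prices inserted domains:

* ``v``   -- V(i,j): best energy of [i,j] with i paired to j;
* ``wm``  -- best energy of [i,j] as multibranch-loop interior content with
  at least one branch (per-branch and per-unpaired-nucleotide costs apply);
* ``we``  -- best energy of [i,j] as exterior-loop content, zero or more
  branches, unpaired nucleotides free;
* ``web`` -- like ``we`` but with at least one branch (an inserted domain
  must contain structure).

Energies are integer tenths of kcal/mol; INF marks forbidden states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .thermo import INF, EnergyParams, encode


@njit(cache=True)
def _motif_t(seq, m, n, p, q, stack4, il, bl, pen4, can, asym, asymcap, maxside):
    """Two-pair motif energy; assumes both pairs canonical. INF if oversized."""
    s1 = n - m - 1
    s2 = p - q - 1
    if s1 > maxside or s2 > maxside:
        return INF
    if s1 == 0 and s2 == 0:
        return stack4[seq[m], seq[p], seq[n], seq[q]]
    if s1 == 0 or s2 == 0:
        size = s1 + s2
        e = bl[size]
        if size == 1:
            e += stack4[seq[m], seq[p], seq[n], seq[q]]
        else:
            e += pen4[seq[m], seq[p]] + pen4[seq[n], seq[q]]
        return e
    a = asym * (s1 - s2 if s1 > s2 else s2 - s1)
    if a > asymcap:
        a = asymcap
    return il[s1 + s2] + a + pen4[seq[m], seq[p]] + pen4[seq[n], seq[q]]


@njit(cache=True)
def _fold_kernel(seq, N, stack4, hp, il, bl, pen4, can,
                 asym, asymcap, maxside, minhp,
                 closure, branch, unp):
    v = np.full((N + 2, N + 2), INF, dtype=np.int32)
    wm = np.full((N + 2, N + 2), INF, dtype=np.int32)
    we = np.zeros((N + 2, N + 2), dtype=np.int32)
    web = np.full((N + 2, N + 2), INF, dtype=np.int32)
    # we[i][j]: exterior content of [i,j]; empty fragments (j < i) cost 0
    for L in range(1, N):
        for i in range(1, N - L + 1):
            j = i + L
            # ---- V ----
            if can[seq[i], seq[j]]:
                best = INF
                loop = j - i - 1
                if loop >= minhp:
                    best = hp[loop] + pen4[seq[i], seq[j]]
                # internal / bulge / stack
                nmax = min(i + maxside + 1, j - 1)
                for n in range(i + 1, nmax + 1):
                    qmin = max(j - maxside - 1, n + 1)
                    for q in range(j - 1, qmin - 1, -1):
                        if v[n, q] < INF:
                            e = v[n, q] + _motif_t(seq, i, n, j, q, stack4,
                                                   il, bl, pen4, can,
                                                   asym, asymcap, maxside)
                            if e < best:
                                best = e
                # multibranch
                for h in range(i + 1, j - 1):
                    if wm[i + 1, h] < INF and wm[h + 1, j - 1] < INF:
                        e = (wm[i + 1, h] + wm[h + 1, j - 1]
                             + closure + branch + pen4[seq[i], seq[j]])
                        if e < best:
                            best = e
                if best > INF:
                    best = INF
                v[i, j] = best
            # ---- WM ----
            best = INF
            if v[i, j] < INF:
                best = v[i, j] + branch + pen4[seq[i], seq[j]]
            if wm[i + 1, j] < INF and wm[i + 1, j] + unp < best:
                best = wm[i + 1, j] + unp
            if wm[i, j - 1] < INF and wm[i, j - 1] + unp < best:
                best = wm[i, j - 1] + unp
            for h in range(i + 1, j - 1):
                if wm[i, h] < INF and wm[h + 1, j] < INF:
                    e = wm[i, h] + wm[h + 1, j]
                    if e < best:
                        best = e
            wm[i, j] = best
    # exterior arrays, all fragments [i,j]
    for i in range(1, N + 1):
        for j in range(i, N + 1):
            best = we[i, j - 1]  # j unpaired, free
            bestb = web[i, j - 1] if j > i else INF
            for h in range(i, j):
                if v[h, j] < INF:
                    e = we[i, h - 1] + v[h, j] + pen4[seq[h], seq[j]]
                    if e < best:
                        best = e
                    if e < bestb:
                        bestb = e
            we[i, j] = best
            web[i, j] = bestb if bestb < INF else INF
    return v, wm, we, web


@njit(cache=True)
def _outside_kernel(seq, N, pi, pj, v, wm, we, pen4, stack4, il, bl, can,
                    asym, asymcap, maxside, closure, branch, unp):
    """Best completion energy outside each canonical pair (pair list pi/pj,
    sorted by decreasing span)."""
    P = pi.shape[0]
    vo = np.full(P, INF, dtype=np.int32)
    for a in range(P):
        i, j = pi[a], pj[a]
        # exterior-loop branch
        best = we[1, i - 1] + we[j + 1, N] + pen4[seq[i], seq[j]]
        for b in range(a):  # only wider pairs can enclose
            p, q = pi[b], pj[b]
            if p < i and q > j and vo[b] < INF:
                # continue the helix / loop motif
                if i - p - 1 <= maxside and q - j - 1 <= maxside:
                    e = vo[b] + _motif_t(seq, p, i, q, j, stack4, il, bl,
                                         pen4, can, asym, asymcap, maxside)
                    if e < best:
                        best = e
                # branch of a multibranch loop closed by p-q
                ll = i - 1 - p
                lr = q - 1 - j
                base = (vo[b] + pen4[seq[p], seq[q]] + closure + 2 * branch
                        + pen4[seq[i], seq[j]])
                if ll > 0 and wm[p + 1, i - 1] < INF:
                    e = base + wm[p + 1, i - 1] + unp * lr
                    if e < best:
                        best = e
                if lr > 0 and wm[j + 1, q - 1] < INF:
                    e = base + unp * ll + wm[j + 1, q - 1]
                    if e < best:
                        best = e
                if (ll > 0 and lr > 0 and wm[p + 1, i - 1] < INF
                        and wm[j + 1, q - 1] < INF):
                    e = base + wm[p + 1, i - 1] + wm[j + 1, q - 1]
                    if e < best:
                        best = e
        vo[a] = best if best < INF else INF
    return vo


def _tables(params: EnergyParams, N: int):
    maxlen = max(2 * params.max_internal_side + 2, N, 31)
    hp, il, bl = params.loop_tables(maxlen)
    stack4 = params.stack4()
    can = np.zeros((4, 4), dtype=np.bool_)
    pen4 = np.zeros((4, 4), dtype=np.int32)
    # A=0 C=1 G=2 U=3
    for a, b in ((0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)):
        can[a, b] = True
        if not ((a, b) == (2, 1) or (a, b) == (1, 2)):
            pen4[a, b] = params.au_gu_end_penalty
    return stack4, hp, il, bl, pen4, can


@dataclass
class SingleFoldTables:
    """DP arrays from :func:`fold_single` plus the allowed-pair mask."""

    seq: np.ndarray  # int8 codes, 1-based
    n: int
    v: np.ndarray
    wm: np.ndarray
    we: np.ndarray
    web: np.ndarray
    allowed: np.ndarray = field(default=None)  # bool (N+2, N+2)

    @property
    def mfe_t(self) -> int:
        return int(self.we[1, self.n]) if self.n >= 1 else 0

    @property
    def mfe(self) -> float:
        return self.mfe_t / 10.0

    def allowed_pair(self, i: int, j: int) -> bool:
        return bool(self.allowed[i, j])


def fold_single(seq: str, params: EnergyParams) -> SingleFoldTables:
    """Fold one sequence; fills V/WM/WE arrays and the minimum free energy.

    The allowed-pair mask starts permissive (every finite V cell); apply
    :func:`filter_pairs` to restrict it.
    """
    codes = encode(seq)
    N = len(seq)
    stack4, hp, il, bl, pen4, can = _tables(params, N)
    v, wm, we, web = _fold_kernel(
        codes, N, stack4, hp, il, bl, pen4, can,
        params.internal_asymmetry, params.internal_asymmetry_cap,
        params.max_internal_side, params.min_hairpin,
        params.mbl_closure, params.mbl_branch, params.mbl_unpaired)
    tables = SingleFoldTables(seq=codes, n=N, v=v, wm=wm, we=we, web=web)
    tables.allowed = v < INF
    return tables


def best_with_pair(tables: SingleFoldTables, params: EnergyParams) -> np.ndarray:
    """(N+2, N+2) array: lowest energy over structures containing each pair."""
    N = tables.n
    stack4, hp, il, bl, pen4, can = _tables(params, N)
    ii, jj = np.nonzero(tables.v < INF)
    order = np.argsort(ii - jj)  # widest span first
    pi = ii[order].astype(np.int64)
    pj = jj[order].astype(np.int64)
    vo = _outside_kernel(
        tables.seq, N, pi, pj, tables.v, tables.wm, tables.we, pen4, stack4,
        il, bl, can, params.internal_asymmetry, params.internal_asymmetry_cap,
        params.max_internal_side, params.mbl_closure, params.mbl_branch,
        params.mbl_unpaired)
    best = np.full((N + 2, N + 2), INF, dtype=np.int32)
    for a in range(len(pi)):
        tot = int(tables.v[pi[a], pj[a]]) + int(vo[a])
        best[pi[a], pj[a]] = min(tot, INF)
    return best


def filter_pairs(seq: str, tables: SingleFoldTables, window_percent: float,
                 params: EnergyParams) -> np.ndarray:
    """Restrict the allowed-pair mask to pairs found in low-energy structures.

    A pair is kept when the best structure containing it lies within
    ``window_percent`` of the minimum free energy; 1.0 (or more) disables
    the filter.  Returns the boolean mask and installs it on ``tables``.
    """
    if window_percent < 0:
        raise ValueError("window_percent must be >= 0")
    finite = tables.v < INF
    if window_percent >= 1.0:
        tables.allowed = finite
        return tables.allowed
    best = best_with_pair(tables, params)
    mfe = tables.mfe_t
    thr = mfe + int(round(window_percent * abs(mfe)))
    tables.allowed = finite & (best <= thr)
    return tables.allowed


# ---------------------------------------------------------------------------
# single-sequence traceback (used for inserted-domain contents and for
# whole-sequence minimum-free-energy structures)

def _assert_found(cond, what, i, j):
    if not cond:
        raise AssertionError(
            f"single-sequence traceback: no recursion term reproduces "
            f"{what}({i},{j})")


def trace_v(t: SingleFoldTables, params: EnergyParams, i: int, j: int,
            out: list) -> None:
    """Recover the pairs of the optimal substructure closed by pair (i, j)."""
    from .thermo import hairpin_energy_t, motif_energy_t, end_penalty_t
    out.append((i, j))
    val = int(t.v[i, j])
    if j - i - 1 >= params.min_hairpin:
        if hairpin_energy_t(t.seq, i, j, params) == val:
            return
    cap = params.max_internal_side
    for n in range(i + 1, min(i + cap + 2, j)):
        for q in range(j - 1, max(j - cap - 2, n), -1):
            if t.v[n, q] >= INF:
                continue
            m = motif_energy_t(t.seq, i, n, j, q, params)
            if m < INF and m + int(t.v[n, q]) == val:
                trace_v(t, params, n, q, out)
                return
    pen = end_penalty_t(t.seq, i, j, params)
    base = params.mbl_closure + params.mbl_branch + pen
    for h in range(i + 1, j - 1):
        if (t.wm[i + 1, h] < INF and t.wm[h + 1, j - 1] < INF
                and int(t.wm[i + 1, h]) + int(t.wm[h + 1, j - 1]) + base == val):
            trace_wm(t, params, i + 1, h, out)
            trace_wm(t, params, h + 1, j - 1, out)
            return
    _assert_found(False, "V", i, j)


def trace_wm(t: SingleFoldTables, params: EnergyParams, i: int, j: int,
             out: list) -> None:
    """Recover the pairs of optimal multibranch-loop content on [i, j]."""
    from .thermo import end_penalty_t
    val = int(t.wm[i, j])
    if t.v[i, j] < INF:
        pen = end_penalty_t(t.seq, i, j, params)
        if int(t.v[i, j]) + params.mbl_branch + pen == val:
            trace_v(t, params, i, j, out)
            return
    if t.wm[i + 1, j] < INF and int(t.wm[i + 1, j]) + params.mbl_unpaired == val:
        trace_wm(t, params, i + 1, j, out)
        return
    if t.wm[i, j - 1] < INF and int(t.wm[i, j - 1]) + params.mbl_unpaired == val:
        trace_wm(t, params, i, j - 1, out)
        return
    for h in range(i + 1, j - 1):
        if (t.wm[i, h] < INF and t.wm[h + 1, j] < INF
                and int(t.wm[i, h]) + int(t.wm[h + 1, j]) == val):
            trace_wm(t, params, i, h, out)
            trace_wm(t, params, h + 1, j, out)
            return
    _assert_found(False, "WM", i, j)


def trace_we(t: SingleFoldTables, params: EnergyParams, i: int, j: int,
             out: list) -> None:
    """Recover the pairs of optimal exterior-loop content on [i, j]."""
    from .thermo import end_penalty_t
    if j < i:
        return
    val = int(t.we[i, j])
    if int(t.we[i, j - 1]) == val:
        trace_we(t, params, i, j - 1, out)
        return
    for h in range(i, j):
        if t.v[h, j] < INF:
            pen = end_penalty_t(t.seq, h, j, params)
            if int(t.we[i, h - 1]) + int(t.v[h, j]) + pen == val:
                trace_v(t, params, h, j, out)
                trace_we(t, params, i, h - 1, out)
                return
    _assert_found(False, "WE", i, j)


def trace_web(t: SingleFoldTables, params: EnergyParams, i: int, j: int,
              out: list) -> None:
    """Like :func:`trace_we` but for content with at least one branch."""
    from .thermo import end_penalty_t
    val = int(t.web[i, j])
    if j > i and t.web[i, j - 1] < INF and int(t.web[i, j - 1]) == val:
        trace_web(t, params, i, j - 1, out)
        return
    for h in range(i, j):
        if t.v[h, j] < INF:
            pen = end_penalty_t(t.seq, h, j, params)
            if int(t.we[i, h - 1]) + int(t.v[h, j]) + pen == val:
                trace_v(t, params, h, j, out)
                trace_we(t, params, i, h - 1, out)
                return
    _assert_found(False, "WEB", i, j)


def mfe_structure(t: SingleFoldTables, params: EnergyParams) -> list:
    """Pair list of one minimum-free-energy structure."""
    out: list = []
    if t.n >= 1:
        trace_we(t, params, 1, t.n, out)
    return sorted(out)
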