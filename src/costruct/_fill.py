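"""Numba kernel for the banded joint fold-and-align dynamic program.

Indices are 1-based nucleotide positions; fragment ends are inclusive.  The
4D arrays V and W are stored band-compressed: the seq2 index k is held as an
offset from ``klo[i]``, the lower edge of the alignment band at seq1
position i.  Energies are integer tenths of kcal/mol, INF = forbidden.

Mode flags: ``use_stackii`` enables stem extensions and loops aligned to
stacked pairs; ``use_domain`` enables inserted-domain moves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .thermo import INF
from .singlefold import _motif_t


@njit(cache=True, inline="always")
def _getv(V, klo, khi, i, j, k, l):
    if k < klo[i] or k > khi[i] or l < klo[j] or l > khi[j]:
        return INF
    return V[i, j, k - klo[i], l - klo[j]]


@njit(cache=True, inline="always")
def _getw(W, klo, khi, i, j, k, l):
    if i > j or k > l:
        return INF
    if k < klo[i] or k > khi[i] or l < klo[j] or l > khi[j]:
        return INF
    return W[i, j, k - klo[i], l - klo[j]]


@njit(cache=True)
def fill_kernel(seq1, seq2, N1, N2, klo, khi, kw,
                allowed1, allowed2, pairin1, pairin2, wm1, wm2, web1, web2,
                stack4, hp, il, bl, pen4, can,
                asym, asymcap, maxside, maxext, minhp,
                closure, branch, unp, gap, opening, elong,
                use_stackii, use_domain):
    V = np.full((N1 + 2, N1 + 2, kw, kw), INF, dtype=np.int32)
    W = np.full((N1 + 2, N1 + 2, kw, kw), INF, dtype=np.int32)

    for L1 in range(0, N1):
        for i in range(1, N1 - L1 + 1):
            j = i + L1
            p1 = pen4[seq1[i], seq1[j]]
            a1ok = allowed1[i, j]
            for L2 in range(0, N2):
                for k in range(max(1, klo[i]), khi[i] + 1):
                    l = k + L2
                    if l > N2 or l < klo[j] or l > khi[j]:
                        continue
                    ko = k - klo[i]
                    lo = l - klo[j]
                    p2 = pen4[seq2[k], seq2[l]]
                    # ---------------- V ----------------
                    best = INF
                    if a1ok and allowed2[k, l]:
                        lp1 = j - i - 1
                        lp2 = l - k - 1
                        # hairpin in both sequences
                        if lp1 >= minhp and lp2 >= minhp:
                            d12 = lp1 - lp2 if lp1 > lp2 else lp2 - lp1
                            e = hp[lp1] + p1 + hp[lp2] + p2 + gap * d12
                            if e < best:
                                best = e
                        # internal/bulge/stack aligned to internal/bulge/stack
                        amax = min(maxside + 1, j - i - 1 - minhp)
                        for a in range(1, amax + 1):
                            ip = i + a
                            for b in range(1, j - ip - minhp + 1):
                                if b > maxside + 1:
                                    break
                                jp = j - b
                                if not allowed1[ip, jp]:
                                    continue
                                m1 = _motif_t(seq1, i, ip, j, jp, stack4, il,
                                              bl, pen4, can, asym, asymcap,
                                              maxside)
                                if m1 >= INF:
                                    continue
                                cmax = min(maxside + 1, l - k - 1 - minhp)
                                klo_ip = klo[ip]
                                khi_ip = khi[ip]
                                klo_jp = klo[jp]
                                khi_jp = khi[jp]
                                for c in range(1, cmax + 1):
                                    kp = k + c
                                    if kp < klo_ip or kp > khi_ip:
                                        continue
                                    for d2 in range(1, l - kp - minhp + 1):
                                        if d2 > maxside + 1:
                                            break
                                        lq = l - d2
                                        if lq < klo_jp or lq > khi_jp:
                                            continue
                                        vv = V[ip, jp, kp - klo_ip,
                                               lq - klo_jp]
                                        if vv >= INF:
                                            continue
                                        m2 = _motif_t(seq2, k, kp, l, lq,
                                                      stack4, il, bl, pen4,
                                                      can, asym, asymcap,
                                                      maxside)
                                        if m2 >= INF:
                                            continue
                                        dac = a - c if a > c else c - a
                                        dbd = b - d2 if b > d2 else d2 - b
                                        e = vv + m1 + m2 + gap * (dac + dbd)
                                        if e < best:
                                            best = e
                        if use_stackii:
                            # helix in one sequence aligned to a loop motif
                            # in the other (lockstep indices, no gaps)
                            for dd in range(2, maxext + 1):
                                ip = i + dd
                                jp = j - dd
                                kp = k + dd
                                lq = l - dd
                                if ip >= jp or kp >= lq:
                                    break
                                vv = _getv(V, klo, khi, ip, jp, kp, lq)
                                if vv >= INF:
                                    continue
                                # seq2 keeps stacking: pairs (k+c, l-c)
                                s2sum = 0
                                for c in range(dd):
                                    s = stack4[seq2[k + c], seq2[l - c],
                                               seq2[k + c + 1], seq2[l - c - 1]]
                                    if s >= INF:
                                        s2sum = INF
                                        break
                                    s2sum += s
                                if s2sum < INF:
                                    m1 = _motif_t(seq1, i, ip, j, jp, stack4,
                                                  il, bl, pen4, can, asym,
                                                  asymcap, maxside)
                                    if m1 < INF:
                                        e = vv + m1 + s2sum
                                        if e < best:
                                            best = e
                                s1sum = 0
                                for c in range(dd):
                                    s = stack4[seq1[i + c], seq1[j - c],
                                               seq1[i + c + 1], seq1[j - c - 1]]
                                    if s >= INF:
                                        s1sum = INF
                                        break
                                    s1sum += s
                                if s1sum < INF:
                                    m2 = _motif_t(seq2, k, kp, l, lq, stack4,
                                                  il, bl, pen4, can, asym,
                                                  asymcap, maxside)
                                    if m2 < INF:
                                        e = vv + m2 + s1sum
                                        if e < best:
                                            best = e
                            # whole motif inserted in one sequence, the other
                            # pair unaligned with gap penalties
                            cmax = min(maxside + 1, l - k - 1 - minhp)
                            for c in range(1, cmax + 1):
                                kp = k + c
                                for d2 in range(1, l - kp - minhp + 1):
                                    if d2 > maxside + 1:
                                        break
                                    lq = l - d2
                                    vv = _getv(V, klo, khi, i, j, kp, lq)
                                    if vv >= INF:
                                        continue
                                    m2 = _motif_t(seq2, k, kp, l, lq, stack4,
                                                  il, bl, pen4, can, asym,
                                                  asymcap, maxside)
                                    if m2 >= INF:
                                        continue
                                    e = vv + m2 + gap * (c + d2)
                                    if e < best:
                                        best = e
                            amax2 = min(maxside + 1, j - i - 1 - minhp)
                            for a in range(1, amax2 + 1):
                                ip = i + a
                                for b in range(1, j - ip - minhp + 1):
                                    if b > maxside + 1:
                                        break
                                    jp = j - b
                                    vv = _getv(V, klo, khi, ip, jp, k, l)
                                    if vv >= INF:
                                        continue
                                    m1 = _motif_t(seq1, i, ip, j, jp, stack4,
                                                  il, bl, pen4, can, asym,
                                                  asymcap, maxside)
                                    if m1 >= INF:
                                        continue
                                    e = vv + m1 + gap * (a + b)
                                    if e < best:
                                        best = e
                        # multibranch: two aligned interior parts
                        mblbase = 2 * closure + 2 * branch + p1 + p2
                        for ip in range(i + 1, j - 1):
                            if not pairin1[ip + 1, j - 1]:
                                break
                            if not pairin1[i + 1, ip]:
                                continue
                            kplo = max(k + 1, klo[ip])
                            kphi = min(l - 2, khi[ip])
                            for kp in range(kplo, kphi + 1):
                                if not pairin2[k + 1, kp]:
                                    continue
                                if not pairin2[kp + 1, l - 1]:
                                    break
                                wl = _getw(W, klo, khi, i + 1, ip, k + 1, kp)
                                if wl >= INF:
                                    continue
                                wr = _getw(W, klo, khi, ip + 1, j - 1,
                                           kp + 1, l - 1)
                                if wr >= INF:
                                    continue
                                e = wl + wr + mblbase
                                if e < best:
                                    best = e
                        if use_domain:
                            dibase = mblbase + opening
                            for kp in range(k + 1, l - 1):
                                if wm2[kp + 1, l - 1] < INF:
                                    w = _getw(W, klo, khi, i + 1, j - 1,
                                              k + 1, kp)
                                    if w < INF:
                                        e = (w + wm2[kp + 1, l - 1] + dibase
                                             + (l - 1 - kp) * elong)
                                        if e < best:
                                            best = e
                                if wm2[k + 1, kp] < INF:
                                    w = _getw(W, klo, khi, i + 1, j - 1,
                                              kp + 1, l - 1)
                                    if w < INF:
                                        e = (w + wm2[k + 1, kp] + dibase
                                             + (kp - k) * elong)
                                        if e < best:
                                            best = e
                            for ip in range(i + 1, j - 1):
                                if wm1[ip + 1, j - 1] < INF:
                                    w = _getw(W, klo, khi, i + 1, ip,
                                              k + 1, l - 1)
                                    if w < INF:
                                        e = (w + wm1[ip + 1, j - 1] + dibase
                                             + (j - 1 - ip) * elong)
                                        if e < best:
                                            best = e
                                if wm1[i + 1, ip] < INF:
                                    w = _getw(W, klo, khi, ip + 1, j - 1,
                                              k + 1, l - 1)
                                    if w < INF:
                                        e = (w + wm1[i + 1, ip] + dibase
                                             + (ip - i) * elong)
                                        if e < best:
                                            best = e
                        V[i, j, ko, lo] = best if best < INF else INF
                    # ---------------- W ----------------
                    # a W fragment must hold at least one conserved branch
                    if not (pairin1[i, j] and pairin2[k, l]):
                        continue
                    best = INF
                    vv = V[i, j, ko, lo]
                    if vv < INF:
                        best = vv + 2 * branch + p1 + p2
                    e = _getw(W, klo, khi, i + 1, j, k, l)
                    if e < INF and e + unp + gap < best:
                        best = e + unp + gap
                    e = _getw(W, klo, khi, i, j - 1, k, l)
                    if e < INF and e + unp + gap < best:
                        best = e + unp + gap
                    e = _getw(W, klo, khi, i, j, k + 1, l)
                    if e < INF and e + unp + gap < best:
                        best = e + unp + gap
                    e = _getw(W, klo, khi, i, j, k, l - 1)
                    if e < INF and e + unp + gap < best:
                        best = e + unp + gap
                    e = _getw(W, klo, khi, i + 1, j, k + 1, l)
                    if e < INF and e + 2 * unp < best:
                        best = e + 2 * unp
                    e = _getw(W, klo, khi, i, j - 1, k, l - 1)
                    if e < INF and e + 2 * unp < best:
                        best = e + 2 * unp
                    for ip in range(i + 1, j):
                        if not pairin1[ip + 1, j]:
                            break
                        if not pairin1[i, ip]:
                            continue
                        kplo = max(k + 1, klo[ip], klo[ip + 1] - 1)
                        kphi = min(l - 1, khi[ip], khi[ip + 1] - 1)
                        klo_ip = klo[ip]
                        klo_ip1 = klo[ip + 1]
                        for kp in range(kplo, kphi + 1):
                            if not pairin2[k, kp]:
                                continue
                            if not pairin2[kp + 1, l]:
                                break
                            wl = W[i, ip, ko, kp - klo_ip]
                            if wl >= INF:
                                continue
                            wr = W[ip + 1, j, kp + 1 - klo_ip1, lo]
                            if wr >= INF:
                                continue
                            if wl + wr < best:
                                best = wl + wr
                    if use_domain:
                        for kp in range(k + 1, l):
                            if wm2[kp + 1, l] < INF:
                                w = _getw(W, klo, khi, i, j, k, kp)
                                if w < INF:
                                    e = (w + wm2[kp + 1, l] + opening
                                         + (l - kp) * elong)
                                    if e < best:
                                        best = e
                            if wm2[k, kp] < INF:
                                w = _getw(W, klo, khi, i, j, kp + 1, l)
                                if w < INF:
                                    e = (w + wm2[k, kp] + opening
                                         + (kp - k + 1) * elong)
                                    if e < best:
                                        best = e
                        for ip in range(i + 1, j):
                            if wm1[ip + 1, j] < INF:
                                w = _getw(W, klo, khi, i, ip, k, l)
                                if w < INF:
                                    e = (w + wm1[ip + 1, j] + opening
                                         + (j - ip) * elong)
                                    if e < best:
                                        best = e
                            if wm1[i, ip] < INF:
                                w = _getw(W, klo, khi, ip + 1, j, k, l)
                                if w < INF:
                                    e = (w + wm1[i, ip] + opening
                                         + (ip - i + 1) * elong)
                                    if e < best:
                                        best = e
                    W[i, j, ko, lo] = best if best < INF else INF

    # ---------------- W5 / W3 ----------------
    W5 = np.full((N1 + 2, N2 + 2), INF, dtype=np.int32)
    W3 = np.full((N1 + 2, N2 + 2), INF, dtype=np.int32)
    for i in range(0, N1 + 1):
        for k in range(klo[i], khi[i] + 1):
            if i == 0 and k == 0:
                W5[0, 0] = 0
                continue
            best = INF
            if i >= 1 and k >= klo[i - 1] and k <= khi[i - 1]:
                e = W5[i - 1, k]
                if e < INF and e + gap < best:
                    best = e + gap
            if k >= 1 and k - 1 >= klo[i] and k - 1 <= khi[i]:
                e = W5[i, k - 1]
                if e < INF and e + gap < best:
                    best = e + gap
            if i >= 1 and k >= 1 and k - 1 >= klo[i - 1] and k - 1 <= khi[i - 1]:
                e = W5[i - 1, k - 1]
                if e < INF and e < best:
                    best = e
            for ip in range(0, i):
                if not allowed1[ip + 1, i]:
                    continue
                kplo = max(0, klo[ip])
                kphi = min(k - 1, khi[ip])
                for kp in range(kplo, kphi + 1):
                    w5 = W5[ip, kp]
                    if w5 >= INF or not allowed2[kp + 1, k]:
                        continue
                    vv = _getv(V, klo, khi, ip + 1, i, kp + 1, k)
                    if vv >= INF:
                        continue
                    e = (w5 + vv + pen4[seq1[ip + 1], seq1[i]]
                         + pen4[seq2[kp + 1], seq2[k]])
                    if e < best:
                        best = e
            if use_domain:
                for ip in range(0, i):
                    if web1[ip + 1, i] < INF and klo[ip] <= k and k <= khi[ip]:
                        e = W5[ip, k]
                        if e < INF:
                            e = (e + web1[ip + 1, i] + opening
                                 + (i - ip) * elong)
                            if e < best:
                                best = e
                for kp in range(0, k):
                    if web2[kp + 1, k] < INF and klo[i] <= kp and kp <= khi[i]:
                        e = W5[i, kp]
                        if e < INF:
                            e = (e + web2[kp + 1, k] + opening
                                 + (k - kp) * elong)
                            if e < best:
                                best = e
            W5[i, k] = best if best < INF else INF

    for j in range(N1 + 1, 0, -1):
        for l in range(khi[j - 1] + 1, klo[j - 1], -1):
            # W3(j, l) covers suffixes [j, N1], [l, N2]; band on (j-1, l-1)
            if j == N1 + 1 and l == N2 + 1:
                W3[j, l] = 0
                continue
            best = INF
            if j <= N1 and klo[j] <= l - 1 and l - 1 <= khi[j]:
                e = W3[j + 1, l]
                if e < INF and e + gap < best:
                    best = e + gap
            if l <= N2 and klo[j - 1] <= l and l <= khi[j - 1]:
                e = W3[j, l + 1]
                if e < INF and e + gap < best:
                    best = e + gap
            if j <= N1 and l <= N2 and klo[j] <= l and l <= khi[j]:
                e = W3[j + 1, l + 1]
                if e < INF and e < best:
                    best = e
            for jp in range(j + 1, N1 + 2):
                if jp <= N1 + 1 and j <= N1 and jp - 1 >= j:
                    if not allowed1[j, jp - 1]:
                        continue
                    lplo = max(l + 1, klo[jp - 1] + 1)
                    lphi = min(N2 + 1, khi[jp - 1] + 1)
                    for lp in range(lplo, lphi + 1):
                        if lp - 1 < l or not allowed2[l, lp - 1]:
                            continue
                        w3 = W3[jp, lp]
                        if w3 >= INF:
                            continue
                        vv = _getv(V, klo, khi, j, jp - 1, l, lp - 1)
                        if vv >= INF:
                            continue
                        e = (w3 + vv + pen4[seq1[j], seq1[jp - 1]]
                             + pen4[seq2[l], seq2[lp - 1]])
                        if e < best:
                            best = e
            if use_domain:
                for jp in range(j + 1, N1 + 2):
                    if web1[j, jp - 1] < INF and klo[jp - 1] <= l - 1 and l - 1 <= khi[jp - 1]:
                        e = W3[jp, l]
                        if e < INF:
                            e = (e + web1[j, jp - 1] + opening
                                 + (jp - j) * elong)
                            if e < best:
                                best = e
                for lp in range(l + 1, N2 + 2):
                    if web2[l, lp - 1] < INF and klo[j - 1] <= lp - 1 and lp - 1 <= khi[j - 1]:
                        e = W3[j, lp]
                        if e < INF:
                            e = (e + web2[l, lp - 1] + opening
                                 + (lp - l) * elong)
                            if e < best:
                                best = e
            W3[j, l] = best if best < INF else INF
    return V, W, W5, W3
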