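"""Traceback of the joint DP: recovers the optimal common structure.

Re-derives, cell by cell, which recursion term attains the stored value and
follows it.  The candidate order is fixed so that ties resolve
deterministically, preferring conserved motifs over stem extensions and
extensions over inserted domains: hairpin, internal/stack, stackII (1-4),
multibranch, domain insertion (1-4).  A cell whose value no term reproduces
raises AssertionError (never a silent mis-trace).
"""

from __future__ import annotations

from .thermo import INF
from .singlefold import trace_wm, trace_web


class _Trace:
    def __init__(self, tables):
        self.t = tables
        self.pairs1 = set()
        self.pairs2 = set()
        self.aligned = []
        self.domains = []

    # -- array accessors with band guards --------------------------------

    def v(self, i, j, k, l):
        return self.t.get_v(i, j, k, l)

    def w(self, i, j, k, l):
        return self.t.get_w(i, j, k, l)

    def w5(self, i, k):
        t = self.t
        if i < 0 or k < 0 or k < t.band.klo[i] or k > t.band.khi[i]:
            return INF
        return int(t.w5_arr[i, k])

    def w3(self, j, l):
        t = self.t
        if j > t.n1 + 1 or l > t.n2 + 1:
            return INF
        if j == t.n1 + 1 and l == t.n2 + 1:
            return 0
        if l - 1 < t.band.klo[j - 1] or l - 1 > t.band.khi[j - 1]:
            return INF
        return int(t.w3_arr[j, l])

    def pen1(self, i, j):
        return int(self.t.pen4[self.t.s1[i], self.t.s1[j]])

    def pen2(self, k, l):
        return int(self.t.pen4[self.t.s2[k], self.t.s2[l]])

    def motif1(self, m, n, p, q):
        return self.t.motif1(m, n, p, q)

    def motif2(self, m, n, p, q):
        return self.t.motif2(m, n, p, q)

    def stack1(self, m, p):
        t = self.t
        return int(t.stack4[t.s1[m], t.s1[p], t.s1[m + 1], t.s1[p - 1]])

    def stack2(self, m, p):
        t = self.t
        return int(t.stack4[t.s2[m], t.s2[p], t.s2[m + 1], t.s2[p - 1]])

    def add_domain(self, host, start, end, context):
        from .core import Domain
        self.domains.append(Domain(host=host, start=start, end=end,
                                   context=context))
        t = self.t
        out = []
        if context == "mbl":
            trace_wm(t.singles1 if host == 1 else t.singles2, t.params,
                     start, end, out)
        else:
            trace_web(t.singles1 if host == 1 else t.singles2, t.params,
                      start, end, out)
        (self.pairs1 if host == 1 else self.pairs2).update(out)

    # -- cell handlers ----------------------------------------------------

    def run(self):
        stack = [("W5", self.t.n1, self.t.n2)]
        while stack:
            item = stack.pop()
            kind = item[0]
            if kind == "W5":
                self.do_w5(item[1], item[2], stack)
            elif kind == "W3":
                self.do_w3(item[1], item[2], stack)
            elif kind == "V":
                self.do_v(item[1], item[2], item[3], item[4],
                          item[5], item[6], item[7], stack)
            else:
                self.do_w(item[1], item[2], item[3], item[4], stack)

    def do_w5(self, i, k, stack):
        if i == 0 and k == 0:
            return
        t = self.t
        p = t.params
        val = self.w5(i, k)
        assert val < INF, f"traceback entered unreachable W5({i},{k})"
        for cand, nxt in (
                (self.w5(i - 1, k) + p.gap_penalty, (i - 1, k)),
                (self.w5(i, k - 1) + p.gap_penalty, (i, k - 1)),
                (self.w5(i - 1, k - 1), (i - 1, k - 1))):
            if cand == val:
                stack.append(("W5",) + nxt)
                return
        for ip in range(0, i):
            if not t.allowed1[ip + 1, i]:
                continue
            for kp in range(max(0, t.band.klo[ip]),
                            min(k - 1, t.band.khi[ip]) + 1):
                if not t.allowed2[kp + 1, k]:
                    continue
                cand = (self.w5(ip, kp) + self.v(ip + 1, i, kp + 1, k)
                        + self.pen1(ip + 1, i) + self.pen2(kp + 1, k))
                if cand == val:
                    stack.append(("W5", ip, kp))
                    stack.append(("V", ip + 1, i, kp + 1, k,
                                  True, True, True))
                    return
        if t.use_domain:
            for ip in range(0, i):
                if t.singles1.web[ip + 1, i] < INF:
                    cand = (self.w5(ip, k) + int(t.singles1.web[ip + 1, i])
                            + p.domain_opening
                            + (i - ip) * p.domain_elongation)
                    if cand == val:
                        self.add_domain(1, ip + 1, i, "exterior")
                        stack.append(("W5", ip, k))
                        return
            for kp in range(0, k):
                if t.singles2.web[kp + 1, k] < INF:
                    cand = (self.w5(i, kp) + int(t.singles2.web[kp + 1, k])
                            + p.domain_opening
                            + (k - kp) * p.domain_elongation)
                    if cand == val:
                        self.add_domain(2, kp + 1, k, "exterior")
                        stack.append(("W5", i, kp))
                        return
        raise AssertionError(f"no recursion term reproduces W5({i},{k})")

    def do_w3(self, j, l, stack):
        t = self.t
        p = t.params
        if j == t.n1 + 1 and l == t.n2 + 1:
            return
        val = self.w3(j, l)
        assert val < INF, f"traceback entered unreachable W3({j},{l})"
        for cand, nxt in (
                (self.w3(j + 1, l) + p.gap_penalty, (j + 1, l)),
                (self.w3(j, l + 1) + p.gap_penalty, (j, l + 1)),
                (self.w3(j + 1, l + 1), (j + 1, l + 1))):
            if cand == val:
                stack.append(("W3",) + nxt)
                return
        for jp in range(j + 1, t.n1 + 2):
            if jp - 1 > t.n1 or not t.allowed1[j, jp - 1]:
                continue
            for lp in range(l + 1, t.n2 + 2):
                if lp - 1 > t.n2 or not t.allowed2[l, lp - 1]:
                    continue
                cand = (self.w3(jp, lp) + self.v(j, jp - 1, l, lp - 1)
                        + self.pen1(j, jp - 1) + self.pen2(l, lp - 1))
                if cand == val:
                    stack.append(("W3", jp, lp))
                    stack.append(("V", j, jp - 1, l, lp - 1,
                                  True, True, True))
                    return
        if t.use_domain:
            for jp in range(j + 1, t.n1 + 2):
                if t.singles1.web[j, jp - 1] < INF:
                    cand = (self.w3(jp, l) + int(t.singles1.web[j, jp - 1])
                            + p.domain_opening
                            + (jp - j) * p.domain_elongation)
                    if cand == val:
                        self.add_domain(1, j, jp - 1, "exterior")
                        stack.append(("W3", jp, l))
                        return
            for lp in range(l + 1, t.n2 + 2):
                if t.singles2.web[l, lp - 1] < INF:
                    cand = (self.w3(j, lp) + int(t.singles2.web[l, lp - 1])
                            + p.domain_opening
                            + (lp - l) * p.domain_elongation)
                    if cand == val:
                        self.add_domain(2, l, lp - 1, "exterior")
                        stack.append(("W3", j, lp))
                        return
        raise AssertionError(f"no recursion term reproduces W3({j},{l})")

    def do_v(self, i, j, k, l, rec1, rec2, aligned, stack):
        t = self.t
        p = t.params
        if rec1:
            self.pairs1.add((i, j))
        if rec2:
            self.pairs2.add((k, l))
        if aligned:
            self.aligned.append((i, j, k, l))
        val = self.v(i, j, k, l)
        assert val < INF
        p1 = self.pen1(i, j)
        p2 = self.pen2(k, l)
        lp1 = j - i - 1
        lp2 = l - k - 1
        minhp = p.min_hairpin
        cap = p.max_internal_side
        gap = p.gap_penalty
        if lp1 >= minhp and lp2 >= minhp:
            cand = (int(t.hp[lp1]) + p1 + int(t.hp[lp2]) + p2
                    + gap * abs(lp1 - lp2))
            if cand == val:
                return
        amax = min(cap + 1, j - i - 1 - minhp)
        for a in range(1, amax + 1):
            ip = i + a
            for b in range(1, min(cap + 1, j - ip - minhp) + 1):
                jp = j - b
                if not t.allowed1[ip, jp]:
                    continue
                m1 = self.motif1(i, ip, j, jp)
                if m1 >= INF:
                    continue
                cmax = min(cap + 1, l - k - 1 - minhp)
                for c in range(1, cmax + 1):
                    kp = k + c
                    for d2 in range(1, min(cap + 1, l - kp - minhp) + 1):
                        lq = l - d2
                        vv = self.v(ip, jp, kp, lq)
                        if vv >= INF:
                            continue
                        m2 = self.motif2(k, kp, l, lq)
                        if m2 >= INF:
                            continue
                        cand = vv + m1 + m2 + gap * (abs(a - c) + abs(b - d2))
                        if cand == val:
                            stack.append(("V", ip, jp, kp, lq,
                                          True, True, True))
                            return
        if t.use_stackii:
            for dd in range(2, p.max_stackII_extension + 1):
                ip, jp, kp, lq = i + dd, j - dd, k + dd, l - dd
                if ip >= jp or kp >= lq:
                    break
                vv = self.v(ip, jp, kp, lq)
                if vv >= INF:
                    continue
                s2sum = 0
                for c in range(dd):
                    s = self.stack2(k + c, l - c)
                    if s >= INF:
                        s2sum = INF
                        break
                    s2sum += s
                if s2sum < INF:
                    m1 = self.motif1(i, ip, j, jp)
                    if m1 < INF and vv + m1 + s2sum == val:
                        for c in range(1, dd):
                            self.pairs2.add((k + c, l - c))
                        stack.append(("V", ip, jp, kp, lq, True, True, True))
                        return
                s1sum = 0
                for c in range(dd):
                    s = self.stack1(i + c, j - c)
                    if s >= INF:
                        s1sum = INF
                        break
                    s1sum += s
                if s1sum < INF:
                    m2 = self.motif2(k, kp, l, lq)
                    if m2 < INF and vv + m2 + s1sum == val:
                        for c in range(1, dd):
                            self.pairs1.add((i + c, j - c))
                        stack.append(("V", ip, jp, kp, lq, True, True, True))
                        return
            cmax = min(cap + 1, l - k - 1 - minhp)
            for c in range(1, cmax + 1):
                kp = k + c
                for d2 in range(1, min(cap + 1, l - kp - minhp) + 1):
                    lq = l - d2
                    vv = self.v(i, j, kp, lq)
                    if vv >= INF:
                        continue
                    m2 = self.motif2(k, kp, l, lq)
                    if m2 < INF and vv + m2 + gap * (c + d2) == val:
                        stack.append(("V", i, j, kp, lq, False, True, False))
                        return
            amax2 = min(cap + 1, j - i - 1 - minhp)
            for a in range(1, amax2 + 1):
                ip = i + a
                for b in range(1, min(cap + 1, j - ip - minhp) + 1):
                    jp = j - b
                    vv = self.v(ip, jp, k, l)
                    if vv >= INF:
                        continue
                    m1 = self.motif1(i, ip, j, jp)
                    if m1 < INF and vv + m1 + gap * (a + b) == val:
                        stack.append(("V", ip, jp, k, l, True, False, False))
                        return
        mblbase = 2 * p.mbl_closure + 2 * p.mbl_branch + p1 + p2
        for ip in range(i + 1, j - 1):
            for kp in range(max(k + 1, t.band.klo[ip]),
                            min(l - 2, t.band.khi[ip]) + 1):
                wl = self.w(i + 1, ip, k + 1, kp)
                if wl >= INF:
                    continue
                wr = self.w(ip + 1, j - 1, kp + 1, l - 1)
                if wr < INF and wl + wr + mblbase == val:
                    stack.append(("W", i + 1, ip, k + 1, kp))
                    stack.append(("W", ip + 1, j - 1, kp + 1, l - 1))
                    return
        if t.use_domain:
            dibase = mblbase + p.domain_opening
            elong = p.domain_elongation
            wm1 = t.singles1.wm
            wm2 = t.singles2.wm
            for kp in range(k + 1, l - 1):
                if wm2[kp + 1, l - 1] < INF:
                    w = self.w(i + 1, j - 1, k + 1, kp)
                    if (w < INF and w + int(wm2[kp + 1, l - 1]) + dibase
                            + (l - 1 - kp) * elong == val):
                        self.add_domain(2, kp + 1, l - 1, "mbl")
                        stack.append(("W", i + 1, j - 1, k + 1, kp))
                        return
            for ip in range(i + 1, j - 1):
                if wm1[ip + 1, j - 1] < INF:
                    w = self.w(i + 1, ip, k + 1, l - 1)
                    if (w < INF and w + int(wm1[ip + 1, j - 1]) + dibase
                            + (j - 1 - ip) * elong == val):
                        self.add_domain(1, ip + 1, j - 1, "mbl")
                        stack.append(("W", i + 1, ip, k + 1, l - 1))
                        return
            for ip in range(i + 1, j - 1):
                if wm1[i + 1, ip] < INF:
                    w = self.w(ip + 1, j - 1, k + 1, l - 1)
                    if (w < INF and w + int(wm1[i + 1, ip]) + dibase
                            + (ip - i) * elong == val):
                        self.add_domain(1, i + 1, ip, "mbl")
                        stack.append(("W", ip + 1, j - 1, k + 1, l - 1))
                        return
            for kp in range(k + 1, l - 1):
                if wm2[k + 1, kp] < INF:
                    w = self.w(i + 1, j - 1, kp + 1, l - 1)
                    if (w < INF and w + int(wm2[k + 1, kp]) + dibase
                            + (kp - k) * elong == val):
                        self.add_domain(2, k + 1, kp, "mbl")
                        stack.append(("W", i + 1, j - 1, kp + 1, l - 1))
                        return
        raise AssertionError(
            f"no recursion term reproduces V({i},{j},{k},{l})")

    def do_w(self, i, j, k, l, stack):
        t = self.t
        p = t.params
        val = self.w(i, j, k, l)
        assert val < INF
        vv = self.v(i, j, k, l)
        if vv < INF and vv + 2 * p.mbl_branch + self.pen1(i, j) \
                + self.pen2(k, l) == val:
            stack.append(("V", i, j, k, l, True, True, True))
            return
        ug = p.mbl_unpaired + p.gap_penalty
        for cand, nxt in (
                (self.w(i + 1, j, k, l) + ug, (i + 1, j, k, l)),
                (self.w(i, j - 1, k, l) + ug, (i, j - 1, k, l)),
                (self.w(i, j, k + 1, l) + ug, (i, j, k + 1, l)),
                (self.w(i, j, k, l - 1) + ug, (i, j, k, l - 1)),
                (self.w(i + 1, j, k + 1, l) + 2 * p.mbl_unpaired,
                 (i + 1, j, k + 1, l)),
                (self.w(i, j - 1, k, l - 1) + 2 * p.mbl_unpaired,
                 (i, j - 1, k, l - 1))):
            if cand == val:
                stack.append(("W",) + nxt)
                return
        for ip in range(i + 1, j):
            for kp in range(max(k + 1, t.band.klo[ip]),
                            min(l - 1, t.band.khi[ip]) + 1):
                wl = self.w(i, ip, k, kp)
                if wl >= INF:
                    continue
                wr = self.w(ip + 1, j, kp + 1, l)
                if wr < INF and wl + wr == val:
                    stack.append(("W", i, ip, k, kp))
                    stack.append(("W", ip + 1, j, kp + 1, l))
                    return
        if t.use_domain:
            elong = p.domain_elongation
            opening = p.domain_opening
            wm1 = t.singles1.wm
            wm2 = t.singles2.wm
            for kp in range(k + 1, l):
                if wm2[kp + 1, l] < INF:
                    w = self.w(i, j, k, kp)
                    if (w < INF and w + int(wm2[kp + 1, l]) + opening
                            + (l - kp) * elong == val):
                        self.add_domain(2, kp + 1, l, "mbl")
                        stack.append(("W", i, j, k, kp))
                        return
            for ip in range(i + 1, j):
                if wm1[ip + 1, j] < INF:
                    w = self.w(i, ip, k, l)
                    if (w < INF and w + int(wm1[ip + 1, j]) + opening
                            + (j - ip) * elong == val):
                        self.add_domain(1, ip + 1, j, "mbl")
                        stack.append(("W", i, ip, k, l))
                        return
            for ip in range(i + 1, j):
                if wm1[i, ip] < INF:
                    w = self.w(ip + 1, j, k, l)
                    if (w < INF and w + int(wm1[i, ip]) + opening
                            + (ip - i + 1) * elong == val):
                        self.add_domain(1, i, ip, "mbl")
                        stack.append(("W", ip + 1, j, k, l))
                        return
            for kp in range(k + 1, l):
                if wm2[k, kp] < INF:
                    w = self.w(i, j, kp + 1, l)
                    if (w < INF and w + int(wm2[k, kp]) + opening
                            + (kp - k + 1) * elong == val):
                        self.add_domain(2, k, kp, "mbl")
                        stack.append(("W", i, j, kp + 1, l))
                        return
        raise AssertionError(
            f"no recursion term reproduces W({i},{j},{k},{l})")


def run_traceback(tables):
    tr = _Trace(tables)
    tr.run()
    return tr
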