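"""Nearest-neighbor thermodynamic model for RNA secondary structure.

A reduced, self-consistent parameter set: sequence-dependent helix stacks,
length-dependent loop initiations with logarithmic extrapolation, a linear
multibranch-loop model, and the three alignment penalties used by the joint
fold-and-align dynamic program (per-gap, domain opening, domain elongation).

All energies are handled internally on a fixed decimal grid of tenths of a
kcal/mol, as integers, so that dynamic-programming comparisons and traceback
ties are exact.  Public functions speak kcal/mol floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Sentinel for "forbidden" in integer-tenths space.  Large enough never to
#: win a minimization, small enough that sums of a few sentinels fit in int32.
INF = 10**8

BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(BASES)}
_CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}

#: Canonical pair codes in a fixed order; index into stack tables.
PAIRS = ("AU", "CG", "GC", "GU", "UA", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGU string as int8 codes, 1-based (slot 0 unused)."""
    try:
        out = np.empty(len(seq) + 1, dtype=np.int8)
        out[0] = -1
        for n, b in enumerate(seq, start=1):
            out[n] = _CODE[b]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None
    return out


def is_canonical(b1: str, b2: str) -> bool:
    """True exactly for the canonical pairs AU, UA, GC, CG, GU, UG."""
    if b1 not in _CODE or b2 not in _CODE:
        raise ValueError(f"nucleotide outside ACGU alphabet: {b1!r}, {b2!r}")
    return b1 + b2 in _CANONICAL


def _t(x: float) -> int:
    """kcal/mol -> integer tenths, with exact decimal rounding."""
    return int(round(x * 10))


@dataclass
class EnergyParams:
    """All thermodynamic constants and alignment penalties, integer tenths.

    ``stack_table[pi, pj]`` is the stack of inner pair ``pj`` on closing pair
    ``pi`` (indices into :data:`PAIRS`).  Loop-initiation tables are indexed
    by loop size and extrapolated logarithmically past their last entry with
    coefficient ``loop_log_coeff``.
    """

    stack_table: np.ndarray  # (6, 6) int32
    hairpin_init: np.ndarray  # index 0..30, int32 (entries < min unused)
    internal_init: np.ndarray  # index 0..30
    bulge_init: np.ndarray  # index 0..30
    au_gu_end_penalty: int = _t(0.5)
    mbl_closure: int = _t(3.4)
    mbl_branch: int = _t(0.4)
    mbl_unpaired: int = _t(0.0)
    gap_penalty: int = _t(0.4)
    domain_opening: int = _t(0.5)
    domain_elongation: int = _t(0.1)
    internal_asymmetry: int = _t(0.6)
    internal_asymmetry_cap: int = _t(3.0)
    loop_log_coeff: int = _t(1.1)
    max_internal_side: int = 20
    max_stackII_extension: int = 5
    min_hairpin: int = 3
    _loop_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for name in ("gap_penalty", "domain_opening", "domain_elongation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- loop initiations with log extrapolation ---------------------------

    def _extrapolate(self, table: np.ndarray, n: int) -> int:
        last = len(table) - 1
        if n <= last:
            v = int(table[n])
            if v >= INF:
                raise KeyError(f"loop initiation undefined for size {n}")
            return v
        return int(table[last]) + _t(self.loop_log_coeff / 10.0 * math.log(n / last))

    def hairpin_init_t(self, n: int) -> int:
        return self._extrapolate(self.hairpin_init, n)

    def internal_init_t(self, n: int) -> int:
        return self._extrapolate(self.internal_init, n)

    def bulge_init_t(self, n: int) -> int:
        return self._extrapolate(self.bulge_init, n)

    def loop_tables(self, maxlen: int):
        """Loop-initiation tables extended to ``maxlen`` (for kernels)."""
        key = ("loops", maxlen)
        if key not in self._loop_cache:
            hp = np.full(maxlen + 1, INF, dtype=np.int32)
            il = np.full(maxlen + 1, INF, dtype=np.int32)
            bl = np.full(maxlen + 1, INF, dtype=np.int32)
            for n in range(1, maxlen + 1):
                if n >= self.min_hairpin:
                    hp[n] = self.hairpin_init_t(n)
                if n >= 2:
                    il[n] = self.internal_init_t(n)
                bl[n] = self.bulge_init_t(n)
            self._loop_cache[key] = (hp, il, bl)
        return self._loop_cache[key]

    def stack4(self) -> np.ndarray:
        """Stack table as a dense (4,4,4,4) base-indexed array for kernels.

        ``stack4[a, b, c, d]`` = stack of pair c-d on closing pair a-b,
        INF where either pair is non-canonical.
        """
        if "stack4" not in self._loop_cache:
            s4 = np.full((4, 4, 4, 4), INF, dtype=np.int32)
            for p1, i1 in _PAIR_INDEX.items():
                for p2, i2 in _PAIR_INDEX.items():
                    s4[_CODE[p1[0]], _CODE[p1[1]], _CODE[p2[0]], _CODE[p2[1]]] = (
                        self.stack_table[i1, i2]
                    )
            self._loop_cache["stack4"] = s4
        return self._loop_cache["stack4"]


# ---------------------------------------------------------------------------
# bundle I/O

_SCALAR_KEYS = {
    "au_gu_end_penalty", "mbl_closure", "mbl_branch", "mbl_unpaired",
    "gap_penalty", "domain_opening", "domain_elongation",
    "internal_asymmetry", "internal_asymmetry_cap", "loop_log_coeff",
}
_INT_KEYS = {"max_internal_side", "max_stackII_extension", "min_hairpin"}


class BundleFormatError(ValueError):
    """Raised for a malformed parameter bundle; names the offending table."""


def load_params(source=None) -> EnergyParams:
    """Load an :class:`EnergyParams` from a plain-text bundle.

    With ``source=None`` the bundle shipped with the package is used, whose
    alignment-penalty defaults are 0.4 kcal/mol per gap, 0.5 kcal/mol per
    inserted-domain opening and 0.1 kcal/mol per inserted-domain nucleotide.
    """
    if source is None:
        text = (resources.files("costruct.data") / "params.txt").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    scalars: dict[str, float] = {}
    stack: dict[tuple[str, str], float] = {}
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "internal": {}, "bulge": {}}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] == "stack":
                p1, p2, v = parts[1], parts[2], float(parts[3])
                if p1 not in _PAIR_INDEX or p2 not in _PAIR_INDEX:
                    raise BundleFormatError(
                        f"stack table: non-canonical pair on line {ln}")
                stack[(p1, p2)] = v
            elif parts[0] in loops:
                loops[parts[0]][int(parts[1])] = float(parts[2])
            elif parts[0] in _SCALAR_KEYS or parts[0] in _INT_KEYS:
                scalars[parts[0]] = float(parts[1])
            else:
                raise BundleFormatError(f"unknown key {parts[0]!r} on line {ln}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, BundleFormatError):
                raise
            raise BundleFormatError(
                f"malformed entry on line {ln}: {raw!r}") from None

    missing = _SCALAR_KEYS - set(scalars)
    if missing:
        raise BundleFormatError(f"missing scalar(s): {sorted(missing)}")
    if len(stack) != 36:
        raise BundleFormatError(
            f"stack table incomplete: {len(stack)}/36 entries")
    for name, tbl in loops.items():
        if not tbl:
            raise BundleFormatError(f"missing {name} initiation table")

    st = np.full((6, 6), INF, dtype=np.int32)
    for (p1, p2), v in stack.items():
        st[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = _t(v)

    def loop_array(tbl: dict[int, float]) -> np.ndarray:
        arr = np.full(max(tbl) + 1, INF, dtype=np.int32)
        for n, v in tbl.items():
            arr[n] = _t(v)
        return arr

    kwargs = {k: (int(v) if k in _INT_KEYS else _t(v)) for k, v in scalars.items()}
    return EnergyParams(
        stack_table=st,
        hairpin_init=loop_array(loops["hairpin"]),
        internal_init=loop_array(loops["internal"]),
        bulge_init=loop_array(loops["bulge"]),
        **kwargs,
    )


def save_params(params: EnergyParams, path) -> None:
    """Write a bundle that :func:`load_params` reads back identically."""
    def f(v):
        return f"{v / 10:g}"
    lines = []
    for k in sorted(_SCALAR_KEYS):
        lines.append(f"{k} {f(getattr(params, k))}")
    for k in sorted(_INT_KEYS):
        lines.append(f"{k} {getattr(params, k)}")
    for p1 in PAIRS:
        for p2 in PAIRS:
            lines.append(
                f"stack {p1} {p2} "
                f"{f(params.stack_table[_PAIR_INDEX[p1], _PAIR_INDEX[p2]])}")
    for name, tbl in (("hairpin", params.hairpin_init),
                      ("internal", params.internal_init),
                      ("bulge", params.bulge_init)):
        for n, v in enumerate(tbl):
            if v < INF:
                lines.append(f"{name} {n} {f(v)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# motif energies (integer-tenths core + float wrappers)

def _pair_ok(seq: np.ndarray, i: int, j: int) -> bool:
    a, b = BASES[seq[i]], BASES[seq[j]]
    return a + b in _CANONICAL


def _require_canonical(seq: np.ndarray, i: int, j: int) -> None:
    if not _pair_ok(seq, i, j):
        raise ValueError(
            f"non-canonical pair {BASES[seq[i]]}{BASES[seq[j]]} at ({i},{j})")


def end_penalty_t(seq: np.ndarray, i: int, j: int, params: EnergyParams) -> int:
    """Helix-end penalty: charged when the i-j closing pair is A-U or G-U."""
    _require_canonical(seq, i, j)
    pair = BASES[seq[i]] + BASES[seq[j]]
    return params.au_gu_end_penalty if pair in ("AU", "UA", "GU", "UG") else 0


def hairpin_energy_t(seq: np.ndarray, i: int, j: int, params: EnergyParams) -> int:
    _require_canonical(seq, i, j)
    loop = j - i - 1
    if loop < params.min_hairpin:
        return INF
    return params.hairpin_init_t(loop) + end_penalty_t(seq, i, j, params)


def _stack_lookup_t(seq: np.ndarray, m: int, n: int, p: int, q: int,
                    params: EnergyParams) -> int:
    outer = BASES[seq[m]] + BASES[seq[p]]
    inner = BASES[seq[n]] + BASES[seq[q]]
    v = params.stack_table[_PAIR_INDEX[outer], _PAIR_INDEX[inner]]
    if v >= INF:
        raise KeyError(f"stack table has no entry for {outer}/{inner}")
    return int(v)


def motif_energy_t(seq: np.ndarray, m: int, n: int, p: int, q: int,
                   params: EnergyParams) -> int:
    """Energy of the two-pair motif closed by m-p (outer) and n-q (inner).

    Dispatches to a helix stack (adjacent pairs), a bulge (one empty side;
    a length-1 bulge keeps the flanking stack and pays no end penalties) or
    an internal loop (size initiation + capped asymmetry + end penalties on
    both closing pairs).  Sides over ``max_internal_side`` return INF.
    """
    if not (m < n < q < p):
        raise ValueError(f"motif indices must satisfy m<n<q<p: {(m, n, p, q)}")
    _require_canonical(seq, m, p)
    _require_canonical(seq, n, q)
    s1 = n - m - 1
    s2 = p - q - 1
    if s1 > params.max_internal_side or s2 > params.max_internal_side:
        return INF
    if s1 == 0 and s2 == 0:
        return _stack_lookup_t(seq, m, n, p, q, params)
    if s1 == 0 or s2 == 0:
        size = s1 + s2
        e = params.bulge_init_t(size)
        if size == 1:
            e += _stack_lookup_t(seq, m, n, p, q, params)
        else:
            e += end_penalty_t(seq, m, p, params) + end_penalty_t(seq, n, q, params)
        return e
    asym = min(params.internal_asymmetry * abs(s1 - s2),
               params.internal_asymmetry_cap)
    return (params.internal_init_t(s1 + s2) + asym
            + end_penalty_t(seq, m, p, params) + end_penalty_t(seq, n, q, params))


def stack_energy_t(seq: np.ndarray, m: int, p: int, params: EnergyParams) -> int:
    """Stack of pair (m+1)-(p-1) on pair m-p; INF when either is non-canonical."""
    if not (_pair_ok(seq, m, p) and _pair_ok(seq, m + 1, p - 1)):
        return INF
    return motif_energy_t(seq, m, m + 1, p, p - 1, params)


# float wrappers -- the public, kcal/mol face of the module

def _as_arr(seq) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else encode(seq)


def end_penalty(seq, i, j, params):
    return end_penalty_t(_as_arr(seq), i, j, params) / 10.0


def hairpin_energy(seq, i, j, params):
    v = hairpin_energy_t(_as_arr(seq), i, j, params)
    return math.inf if v >= INF else v / 10.0


def motif_energy(seq, m, n, p, q, params):
    v = motif_energy_t(_as_arr(seq), m, n, p, q, params)
    return math.inf if v >= INF else v / 10.0


def stack_energy(seq, m, p, params):
    v = stack_energy_t(_as_arr(seq), m, p, params)
    return math.inf if v >= INF else v / 10.0
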