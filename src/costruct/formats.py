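"""Readers and writers: FASTA, CT, dot-bracket, pairwise alignment.

All coordinates are 1-based.  CT is the standard 6-column connectivity
table.  The pairwise-alignment micro-format has two gapped rows over a
shared column space; nucleotides of conserved (aligned) base pairs are
written uppercase, all other nucleotides lowercase, gaps as '-'; inserted
domains and the gap count are recorded in '#' header lines, so a round
trip recovers the conserved-pair mapping, n_gap and the domain list
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO


class FormatError(ValueError):
    pass


_ALPHABET = set("ACGU")


def _normalize(seq: str, where: str) -> str:
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s, start=1):
        if ch not in _ALPHABET:
            raise FormatError(
                f"{where}: invalid character {ch!r} at position {pos}")
    return s


def read_fasta(source):
    """Parse FASTA into a list of (id, sequence) with a U/uppercase
    alphabet; rejects empty input, duplicate ids and ambiguity codes."""
    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    records = []
    seen = set()
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(records, path_or_handle):
    text = "".join(f">{rid}\n{seq}\n" for rid, seq in records)
    _write_text(text, path_or_handle)
    return text


def _write_text(text, target):
    if target is None:
        return
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


@dataclass
class StructureRecord:
    """One sequence with one pseudoknot-free pair list (1-based)."""

    seq_id: str
    residues: str
    pairs: list = field(default_factory=list)
    energy: float = None

    def __post_init__(self):
        self.residues = _normalize(self.residues, self.seq_id)
        self.pairs = sorted(tuple(p) for p in self.pairs)
        n = len(self.residues)
        partner = [0] * (n + 1)
        for (a, b) in self.pairs:
            if not (1 <= a < b <= n):
                raise FormatError(f"{self.seq_id}: pair {(a, b)} out of range")
            if partner[a] or partner[b]:
                raise FormatError(
                    f"{self.seq_id}: nucleotide in two pairs at {(a, b)}")
            partner[a] = b
            partner[b] = a
        stack = []
        for x in range(1, n + 1):
            if partner[x] > x:
                stack.append(partner[x])
            elif partner[x] and partner[x] < x:
                if not stack or stack[-1] != x:
                    raise FormatError(
                        f"{self.seq_id}: crossing pairs at position {x}")
                stack.pop()


# ---------------------------------------------------------------------------
# CT

def read_ct(source) -> StructureRecord:
    text = source.read() if hasattr(source, "read") else open(source).read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError):
        raise FormatError("CT header must start with the sequence length")
    energy = None
    if "ENERGY" in lines[0]:
        try:
            energy = float(lines[0].split("=")[1].split()[0])
        except (IndexError, ValueError):
            pass
    title = head[-1] if len(head) > 1 and head[-1] != "=" else "seq"
    if len(lines) - 1 != n:
        raise FormatError(f"CT: expected {n} data lines, got {len(lines) - 1}")
    residues = []
    partner = {}
    for ln in lines[1:]:
        f = ln.split()
        if len(f) < 6:
            raise FormatError(f"CT: short data line {ln!r}")
        idx, base, p = int(f[0]), f[1], int(f[4])
        residues.append(base)
        if p < 0 or p > n:
            raise FormatError(f"CT: partner index {p} out of range on {idx}")
        partner[idx] = p
    pairs = []
    for idx, p in partner.items():
        if p:
            if partner.get(p) != idx:
                raise FormatError(
                    f"CT: asymmetric pairing {idx}->{p} but {p}->{partner.get(p)}")
            if idx < p:
                pairs.append((idx, p))
    return StructureRecord(seq_id=title, residues="".join(residues),
                           pairs=pairs, energy=energy)


def write_ct(record: StructureRecord, target=None) -> str:
    n = len(record.residues)
    partner = [0] * (n + 2)
    for (a, b) in record.pairs:
        partner[a] = b
        partner[b] = a
    head = f"{n}"
    if record.energy is not None:
        head += f"  ENERGY = {record.energy:.1f}"
    head += f"  {record.seq_id}"
    out = [head]
    for x in range(1, n + 1):
        nxt = x + 1 if x < n else 0
        out.append(f"{x} {record.residues[x - 1]} {x - 1} {nxt} "
                   f"{partner[x]} {x}")
    text = "\n".join(out) + "\n"
    _write_text(text, target)
    return text


# ---------------------------------------------------------------------------
# dot-bracket

def read_dotbracket(source) -> StructureRecord:
    text = source.read() if hasattr(source, "read") else open(source).read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty dot-bracket input")
    if lines[0].startswith(">"):
        seq_id = lines[0][1:].split()[0]
        lines = lines[1:]
    else:
        seq_id = "seq"
    if len(lines) < 2:
        raise FormatError("dot-bracket needs a sequence and a structure line")
    residues, struct = lines[0], lines[1]
    if len(residues) != len(struct):
        raise FormatError("sequence and structure lengths differ")
    pairs = []
    stack = []
    for pos, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"invalid structure character {ch!r} at {pos}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return StructureRecord(seq_id=seq_id, residues=residues,
                           pairs=sorted(pairs))


def write_dotbracket(record: StructureRecord, target=None) -> str:
    marks = ["."] * len(record.residues)
    for (a, b) in record.pairs:
        marks[a - 1] = "("
        marks[b - 1] = ")"
    text = f">{record.seq_id}\n{record.residues}\n{''.join(marks)}\n"
    _write_text(text, target)
    return text


# ---------------------------------------------------------------------------
# pairwise alignment with inserted-domain annotation

def write_alignment(cs, seq1: str, seq2: str, target=None,
                    ids=("seq1", "seq2")) -> str:
    """Two gapped rows; conserved-pair nucleotides uppercase, the rest
    lowercase; '-' for gaps; headers carry n_gap and domain intervals."""
    n1, n2 = len(seq1), len(seq2)
    anchors = [(0, 0)] + cs.alignment_pairs + [(n1 + 1, n2 + 1)]
    for (a, b), (c, d) in zip(anchors, anchors[1:]):
        if not (a < c and b < d):
            raise FormatError("alignment mapping is not monotone")
    dom_pos = {1: set(), 2: set()}
    for d in cs.domains:
        dom_pos[d.host].update(range(d.start, d.end + 1))
    upper1 = {i for (i, _) in cs.alignment_pairs}
    upper2 = {k for (_, k) in cs.alignment_pairs}
    row1 = []
    row2 = []

    def emit(i, k):
        if i is None:
            row1.append("-")
        else:
            ch = seq1[i - 1]
            row1.append(ch.upper() if i in upper1 else ch.lower())
        if k is None:
            row2.append("-")
        else:
            ch = seq2[k - 1]
            row2.append(ch.upper() if k in upper2 else ch.lower())

    for (a, b), (c, d) in zip(anchors, anchors[1:]):
        i, k = a + 1, b + 1
        while i < c or k < d:
            if i < c and i in dom_pos[1]:
                emit(i, None)
                i += 1
            elif k < d and k in dom_pos[2]:
                emit(None, k)
                k += 1
            elif i < c and k < d:
                emit(i, k)
                i += 1
                k += 1
            elif i < c:
                emit(i, None)
                i += 1
            else:
                emit(None, k)
                k += 1
        if c <= n1:
            emit(c, d)
    head = [f"# n_gap {cs.n_gap}"]
    for d in cs.domains:
        head.append(f"# domain host={d.host} start={d.start} end={d.end} "
                    f"context={d.context}")
    text = "\n".join(head + [f">{ids[0]}", "".join(row1),
                             f">{ids[1]}", "".join(row2)]) + "\n"
    _write_text(text, target)
    return text


def read_alignment(source):
    """Recover (mapping, n_gap, domains) from :func:`write_alignment` text.

    The mapping is the list of (i, k) columns where both nucleotides are
    uppercase (conserved base-paired positions).
    """
    text = source.read() if hasattr(source, "read") else open(source).read()
    n_gap = None
    domains = []
    rows = []
    for ln in text.splitlines():
        if ln.startswith("# n_gap"):
            n_gap = int(ln.split()[2])
        elif ln.startswith("# domain"):
            kv = dict(part.split("=") for part in ln.split()[2:])
            domains.append((int(kv["host"]), int(kv["start"]),
                            int(kv["end"]), kv.get("context", "exterior")))
        elif ln.startswith(">") or not ln.strip():
            continue
        else:
            rows.append(ln.strip())
    if len(rows) != 2 or len(rows[0]) != len(rows[1]):
        raise FormatError("alignment must have two equal-length rows")
    mapping = []
    i = k = 0
    for c1, c2 in zip(rows[0], rows[1]):
        if c1 != "-":
            i += 1
        if c2 != "-":
            k += 1
        if c1 == "-" and c2 == "-":
            raise FormatError("column with two gaps")
        if c1 != "-" and c2 != "-" and c1.isupper() and c2.isupper():
            mapping.append((i, k))
    return mapping, n_gap, domains
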