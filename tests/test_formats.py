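"""Format round trips: FASTA, CT, dot-bracket, pairwise alignment."""

import io

import pytest

from costruct import formats
from costruct.formats import FormatError, StructureRecord
from conftest import random_seq, random_structure


def test_read_fasta_basics():
    recs = formats.read_fasta(io.StringIO(">a\nacgu\n"))
    assert recs == [("a", "ACGU")]
    recs = formats.read_fasta(io.StringIO(">a\nACGT\n"))
    assert recs == [("a", "ACGU")]


def test_read_fasta_errors():
    with pytest.raises(FormatError, match="position 4"):
        formats.read_fasta(io.StringIO(">a\nACGN\n"))
    with pytest.raises(FormatError, match="duplicate"):
        formats.read_fasta(io.StringIO(">a\nAC\n>a\nGU\n"))
    with pytest.raises(FormatError):
        formats.read_fasta(io.StringIO(""))


def test_ct_unpaired_record():
    rec = StructureRecord(seq_id="x", residues="ACGU", pairs=[])
    text = formats.write_ct(rec)
    lines = text.strip().splitlines()
    assert len(lines) == 5
    assert all(ln.split()[4] == "0" for ln in lines[1:])


def test_ct_round_trip_random(rng):
    for _ in range(30):
        n = rng.randint(5, 40)
        rec = StructureRecord(seq_id=f"r{n}", residues=random_seq(rng, n),
                              pairs=random_structure(rng, n))
        back = formats.read_ct(io.StringIO(formats.write_ct(rec)))
        assert back.residues == rec.residues and back.pairs == rec.pairs


def test_ct_asymmetric_pairing_rejected():
    text = "3 x\n1 G 0 2 3 1\n2 A 1 3 0 2\n3 C 2 0 2 3\n"
    # 1<->3 claimed by line 1 but line 3 pairs back to 2
    with pytest.raises(FormatError, match="asymmetric"):
        formats.read_ct(io.StringIO(text))


def test_ct_crossing_rejected():
    rec_text = "4 x\n1 G 0 2 3 1\n2 G 1 3 4 2\n3 C 2 4 1 3\n4 C 3 0 2 4\n"
    with pytest.raises(FormatError, match="crossing"):
        formats.read_ct(io.StringIO(rec_text))


def test_dotbracket_round_trip():
    rec = formats.read_dotbracket(io.StringIO(">s\nGGAAACC\n((...))\n"))
    assert rec.pairs == [(1, 7), (2, 6)]
    assert formats.read_dotbracket(
        io.StringIO(formats.write_dotbracket(rec))).pairs == rec.pairs
    rec = formats.read_dotbracket(io.StringIO(">s\nACGU\n....\n"))
    assert rec.pairs == []


def test_dotbracket_unbalanced():
    with pytest.raises(FormatError):
        formats.read_dotbracket(io.StringIO(">s\nGGA\n((.\n"))


def test_alignment_identical_no_gaps(params):
    from costruct import predict, PredictConfig
    seq = "GGGGAAAACCCC"
    cs = predict(seq, seq, PredictConfig(band_width=24, window_percent=1.0))
    text = formats.write_alignment(cs, seq, seq)
    rows = [ln for ln in text.splitlines() if not ln.startswith(("#", ">"))]
    assert rows[0].upper() == rows[1].upper() == seq
    assert "-" not in rows[0]
    mapping, n_gap, doms = formats.read_alignment(io.StringIO(text))
    assert mapping == cs.alignment_pairs
    assert n_gap == 0 and doms == []
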