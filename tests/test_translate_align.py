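"""Six-frame translation, the local-alignment kernel and e-values,
checked against independent DP and Biopython oracles."""

import math
import random

import pytest

from cogannot.cogdb import CogDatabase, ProteinRecord
from cogannot.io_formats import ReadRecord
from cogannot.translate_align import (
    SearchConfig,
    local_align,
    reverse_complement,
    score_to_evalue,
    search_read,
    six_frame_translate,
)

from dp_oracle import biopython_local_score, oracle_local_score, oracle_segmented_score

AAS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize(
    "nt, frame, expected",
    [
        ("ATGAAA", 1, "MK"),
        ("ATGAAA", -1, "FH"),  # reverse complement TTTCAT
        ("ATGTAA", 1, "M*"),
        ("ATGAAAC", 1, "MK"),  # trailing partial codon dropped
        ("ATGANA", 1, "MX"),  # N-containing codon is ambiguous
    ],
)
def test_six_frame_examples(nt, frame, expected):
    assert six_frame_translate(nt)[frame] == expected


def test_six_frame_structure():
    frames = six_frame_translate("atgaaacccggg")  # lowercase accepted
    assert set(frames) == {1, 2, 3, -1, -2, -3}
    assert frames[1] == "MKPG"
    assert len(frames[2]) == len(frames[3]) == 3


def test_six_frame_rejects_invalid_symbol():
    with pytest.raises(ValueError, match="R"):
        six_frame_translate("ATGRAA")


def test_local_align_identical_triplet():
    aln = local_align("MKW", "MKW")
    assert aln.raw_score == 21  # BLOSUM62 diagonal 5 + 5 + 11
    assert aln.identity_fraction == 1.0
    assert (aln.q_start, aln.q_end, aln.s_start, aln.s_end) == (1, 3, 1, 3)


def test_local_align_zero_floor():
    aln = local_align("KKKK", "DDDD")
    assert aln.raw_score == 0
    assert aln.identity_fraction == 0.0


def test_local_align_rejects_empty():
    with pytest.raises(ValueError):
        local_align("", "MKW")


def test_local_align_never_crosses_stop():
    # the W*W query would score 22 if the stop could be crossed; each
    # stop-free segment alone scores 11
    aln = local_align("W*W", "WCW")
    assert aln.raw_score == 11
    assert oracle_segmented_score("W*W", "WCW") == 11


@pytest.mark.parametrize("trial", range(30))
def test_local_align_matches_independent_oracles(trial):
    """Kernel scores equal both a hand-coded full-matrix DP and
    Biopython's local aligner on random mutated peptide pairs."""
    rng = random.Random(1000 + trial)
    n = rng.randint(5, 50)
    q = "".join(rng.choice(AAS) for _ in range(n))
    s = list(q + "".join(rng.choice(AAS) for _ in range(rng.randint(0, 20))))
    for i in range(len(s)):  # mutate ~20% of sites
        if rng.random() < 0.2:
            s[i] = rng.choice(AAS)
    s = "".join(s)
    score = local_align(q, s).raw_score
    assert score == oracle_local_score(q, s)
    assert score == biopython_local_score(q, s)


def test_score_to_evalue_zero_score():
    bit, ev = score_to_evalue(0, 100, 100)
    assert ev == pytest.approx(0.041 * 100 * 100)
    assert bit == pytest.approx(-math.log(0.041) / math.log(2))


def test_score_to_evalue_linear_in_n():
    _, e1 = score_to_evalue(30, 50, 1000)
    _, e2 = score_to_evalue(30, 50, 2000)
    assert e2 / e1 == pytest.approx(2.0)


def test_score_to_evalue_monotone_in_score():
    _, e40 = score_to_evalue(40, 50, 1000)
    _, e50 = score_to_evalue(50, 50, 1000)
    assert e50 < e40


def test_score_to_evalue_rejects_empty_space():
    with pytest.raises(ValueError):
        score_to_evalue(10, 0, 100)


def _toy_db():
    rng = random.Random(42)
    proteins = [
        ProteinRecord(
            protein_id=f"p{i:02d}",
            aa_sequence="".join(rng.choice(AAS) for _ in range(80)),
            cog_id=f"COG{i:04d}",
            categories=frozenset({"C"}),
        )
        for i in range(10)
    ]
    return CogDatabase(proteins)


def _reverse_translate(peptide, rng):
    from cogannot.synthetic import _inverse_code
    from cogannot.translate_align import ScoringScheme

    inv = _inverse_code(ScoringScheme())
    return "".join(rng.choice(inv[aa]) for aa in peptide)


def test_search_read_finds_planted_protein():
    db = _toy_db()
    rng = random.Random(0)
    source = db.proteins[3]
    read = ReadRecord("r1", _reverse_translate(source.aa_sequence[10:50], rng))
    hit = search_read(read, db)
    assert hit is not None
    assert hit.subject_id == source.protein_id
    assert hit.evalue < 1e-5
    assert hit.frame == 1


def test_search_read_random_read_unassigned():
    db = _toy_db()
    rng = random.Random(5)
    read = ReadRecord("r1", "".join(rng.choice("ACGT") for _ in range(60)))
    assert search_read(read, db) is None


def test_search_read_tiebreak_lexicographic():
    seq = "MKWMKWMKWMKWMKWMKWMKW"
    proteins = [
        ProteinRecord("pb", seq, "COG0002", frozenset({"C"})),
        ProteinRecord("pa", seq, "COG0001", frozenset({"C"})),
    ]
    db = CogDatabase(proteins)
    read = ReadRecord("r1", _reverse_translate(seq, random.Random(1)))
    hit = search_read(read, db)
    assert hit.subject_id == "pa"


def test_search_read_empty_db_and_short_read():
    db = _toy_db()
    with pytest.raises(ValueError):
        search_read(ReadRecord("r1", "ATGATG"), CogDatabase([]))
    assert search_read(ReadRecord("r1", "AT"), db) is None


def test_strand_symmetry():
    """A read and its reverse complement hit the same subject with the
    same score; the frame swaps sign."""
    db = _toy_db()
    rng = random.Random(2)
    source = db.proteins[5]
    fwd = ReadRecord("f", _reverse_translate(source.aa_sequence[5:45], rng))
    rev = ReadRecord("r", reverse_complement(fwd.nt_sequence))
    hf = search_read(fwd, db)
    hr = search_read(rev, db)
    assert hf is not None and hr is not None
    assert hf.subject_id == hr.subject_id
    assert hf.raw_score == hr.raw_score
    assert hf.frame == -hr.frame


def test_heuristic_mode_never_invents_hits():
    """Any heuristic-mode hit is reproduced by the exact engine at the
    identical score, and exact mode is at least as sensitive."""
    db = _toy_db()
    rng = random.Random(3)
    exact = SearchConfig(engine_mode="exact")
    heur = SearchConfig(engine_mode="heuristic")
    for i in range(8):
        source = db.proteins[i]
        read = ReadRecord(f"r{i}", _reverse_translate(source.aa_sequence[i : i + 40], rng))
        he = search_read(read, db, exact)
        hh = search_read(read, db, heur)
        if hh is not None:
            assert he is not None
            assert he.evalue <= hh.evalue
            sub_db = CogDatabase([db.by_id[hh.subject_id]])
            confirm = search_read(read, sub_db, exact)
            assert confirm is not None
            assert confirm.raw_score == hh.raw_score
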