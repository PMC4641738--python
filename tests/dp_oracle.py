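"""Independent oracles used only by the tests.

These deliberately re-derive the quantities the package computes via a
different route: a hand-coded pure-Python full-matrix affine-gap DP for
local alignment scores, Biopython's Seq machinery for translation, and
Biopython's PairwiseAligner for identity counting.  None of them share
code with the package's alignment kernel.
"""

import math

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")


def score_pair(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return -1
    return int(_BLOSUM[a, b])


def oracle_local_score(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Full-matrix Smith-Waterman with affine gaps (gap of length k
    costs gap_open + k * gap_extend); score only."""
    m, n = len(q), len(s)
    NEG = float("-inf")
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0, H[i - 1][j - 1] + score_pair(q[i - 1], s[j - 1]), E[i][j], F[i][j]
            )
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def oracle_segmented_score(q: str, s: str) -> int:
    """Best local score with stop codons segmenting both sequences."""
    best = 0
    for q_seg in q.split("*"):
        for s_seg in s.split("*"):
            if q_seg and s_seg:
                best = max(best, oracle_local_score(q_seg, s_seg))
    return best


def oracle_six_frames(read_seq: str) -> list[str]:
    """Six-frame translation via Biopython."""
    peptides = []
    for strand_seq in (Seq(read_seq), Seq(read_seq).reverse_complement()):
        for off in range(3):
            sub = strand_seq[off : off + (len(strand_seq) - off) // 3 * 3]
            peptides.append(str(sub.translate()))
    return peptides


def oracle_best_hit(read_seq, db, threshold=1e-5, lambda_=0.267, kappa=0.041):
    """Exhaustive best sub-threshold hit over all frames and subjects.

    Returns (evalue, raw_score, subject_id) or None; ties broken like
    the engine (smaller e-value, larger score, lexicographic subject).
    """
    n_db = sum(len(p.aa_sequence) for p in db.proteins)
    best = None
    for pep in oracle_six_frames(read_seq):
        m = len(pep)
        if m == 0:
            continue
        for p in db.proteins:
            sc = oracle_segmented_score(pep, p.aa_sequence)
            if sc <= 0:
                continue
            ev = kappa * m * n_db * math.exp(-lambda_ * sc)
            if ev >= threshold:
                continue
            key = (ev, -sc, p.protein_id)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[0], -best[1], best[2]


_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = _BLOSUM
_aligner.open_gap_score = -12
_aligner.extend_gap_score = -1


def biopython_local_score(q: str, s: str) -> int:
    """Second independent route for stop-free peptides."""
    return int(_aligner.score(q, s))


def biopython_identity(a: str, b: str) -> float:
    """Matched columns of the best local alignment over the shorter
    sequence length, via Biopython's aligner."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / min(len(a), len(b))
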