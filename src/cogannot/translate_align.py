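"""Translated homology search: six-frame translation, local protein
alignment and Karlin-Altschul e-values.

This is the built-in search engine behind the annotation workflows.  A
nucleotide read is translated in all six frames, each frame is split
into stop-free peptide segments, and every segment is locally aligned
(Smith-Waterman, affine gaps, BLOSUM62 by default) against the protein
database.  Raw scores are converted to bit scores and e-values with the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S), and the best
hit below a user threshold wins.

Two engine modes are provided: ``exact`` evaluates every subject, while
``heuristic`` only aligns subjects that share at least one k-peptide
seed word with some frame of the query (it can miss hits but never
invents or rescores one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from ._kernels import sw_align, sw_score

if TYPE_CHECKING:  # pragma: no cover
    from .cogdb import CogDatabase
    from .io_formats import ReadRecord

logger = logging.getLogger(__name__)

#: Amino-acid alphabet used for matrix indexing; X (index 20) is the
#: catch-all for ambiguous translation and never scores positively.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_INDEX = AA_INDEX["X"]

NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)

# module-level alignment call counter; lets tests assert that the
# mapping phase performs no alignment work
_ALIGNMENT_CALLS = 0


def alignment_call_count() -> int:
    """Number of alignment-kernel invocations since the last reset."""
    return _ALIGNMENT_CALLS


def reset_alignment_call_count() -> None:
    global _ALIGNMENT_CALLS
    _ALIGNMENT_CALLS = 0


def _count_alignment_call(n: int = 1) -> None:
    global _ALIGNMENT_CALLS
    _ALIGNMENT_CALLS += n


def _default_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 amino acids, with every pair
    involving X forced to -1 so ambiguous residues never score."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.empty((21, 21), dtype=np.int64)
    for a, i in AA_INDEX.items():
        for b, j in AA_INDEX.items():
            if a == "X" or b == "X":
                mat[i, j] = -1
            else:
                mat[i, j] = int(blosum[a, b])
    return mat


def _standard_genetic_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = "*"
    return code


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus the Karlin-Altschul constants
    used for e-values.

    Defaults are the standard gapped-BLOSUM62 values (gap open -11,
    extend -1, lambda 0.267, K 0.041); they are fixed constants rather
    than fitted, which is adequate because every comparison the
    workflows make is internal to this engine.
    """

    substitution_matrix: np.ndarray = field(default_factory=_default_matrix)
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    kappa: float = 0.041
    genetic_code: dict[str, str] = field(default_factory=_standard_genetic_code)

    def __post_init__(self) -> None:
        mat = self.substitution_matrix
        if mat.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 (20 aa + X)")
        if not np.array_equal(mat, mat.T):
            raise ValueError("substitution matrix must be symmetric")
        if (mat[X_INDEX, :] > 0).any():
            raise ValueError("pairs involving X must score <= 0")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.lambda_ <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")

    @property
    def first_gap(self) -> int:
        """Score of the first column of a gap (open + extend)."""
        return self.gap_open + self.gap_extend


@dataclass(frozen=True)
class SearchConfig:
    """User-facing search knobs.

    ``evalue_threshold`` defaults to 1e-5, the conventional cut-off for
    translated searches of short reads.  ``seed_word_length`` only
    matters in heuristic mode.
    """

    evalue_threshold: float = 1e-5
    engine_mode: str = "exact"
    seed_word_length: int = 4
    max_hits_retained: int = 1

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.engine_mode not in ("exact", "heuristic", "external"):
            raise ValueError(f"unknown engine_mode {self.engine_mode!r}")
        if self.seed_word_length < 2:
            raise ValueError("seed_word_length must be >= 2")
        if self.max_hits_retained < 1:
            raise ValueError("max_hits_retained must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search hit (best local alignment of one read
    frame segment against one subject protein)."""

    query_id: str
    subject_id: str
    frame: int
    raw_score: int
    bit_score: float
    evalue: float
    q_aa_start: int
    q_aa_end: int
    s_start: int
    s_end: int
    identity_fraction: float


@dataclass(frozen=True)
class LocalAlignment:
    raw_score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_matches: int
    n_columns: int

    @property
    def identity_fraction(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide to matrix indices; unknown residues become X."""
    return np.array([AA_INDEX.get(aa, X_INDEX) for aa in peptide], dtype=np.int64)


def reverse_complement(nt_sequence: str) -> str:
    return nt_sequence.translate(NT_COMPLEMENT)[::-1]


def six_frame_translate(
    nt_sequence: str, scheme: Optional[ScoringScheme] = None
) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1/+2/+3 read the given strand at offsets 0/1/2; -1/-2/-3
    read the reverse complement the same way.  Stop codons are rendered
    '*'; codons containing N translate to 'X'; a trailing partial codon
    is dropped.
    """
    code = (scheme or _DEFAULT_SCHEME).genetic_code
    seq = nt_sequence.upper()
    for ch in set(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid nucleotide {ch!r} in sequence")
    rc = reverse_complement(seq)
    frames: dict[int, str] = {}
    for strand_seq, sign in ((seq, 1), (rc, -1)):
        for offset in range(3):
            aas = []
            for i in range(offset, len(strand_seq) - 2, 3):
                codon = strand_seq[i : i + 3]
                aas.append(code.get(codon, "X") if "N" not in codon else "X")
            frames[sign * (offset + 1)] = "".join(aas)
    return frames


def _stop_free_segments(peptide: str) -> list[tuple[int, str]]:
    """Split a peptide at stop codons; yields (0-based offset, segment)."""
    segments = []
    start = 0
    for i, aa in enumerate(peptide + "*"):
        if aa == "*":
            if i > start:
                segments.append((start, peptide[start:i]))
            start = i + 1
    return segments


def local_align(
    query_peptide: str, subject_peptide: str, scheme: Optional[ScoringScheme] = None
) -> LocalAlignment:
    """Maximum-scoring local alignment under affine gaps.

    Stop codons segment both sequences: the optimum is taken over all
    stop-free segment pairs, so an alignment never crosses a '*'.
    Returns the zero alignment when no positive-scoring pair exists.
    """
    if not query_peptide or not subject_peptide:
        raise ValueError("peptides must be non-empty")
    scheme = scheme or _DEFAULT_SCHEME
    mat = scheme.substitution_matrix
    best = LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    for q_off, q_seg in _stop_free_segments(query_peptide):
        q_enc = encode_peptide(q_seg)
        for s_off, s_seg in _stop_free_segments(subject_peptide):
            _count_alignment_call()
            score, qs, qe, ss, se, n_match, n_col = sw_align(
                q_enc, encode_peptide(s_seg), mat, scheme.first_gap, scheme.gap_extend
            )
            if score > best.raw_score:
                best = LocalAlignment(
                    int(score), qs + q_off, qe + q_off, ss + s_off, se + s_off,
                    int(n_match), int(n_col),
                )
    return best


def score_to_evalue(
    raw_score: int, m: int, n: int, scheme: Optional[ScoringScheme] = None
) -> tuple[float, float]:
    """Karlin-Altschul statistics: returns (bit_score, evalue) for a raw
    score in a search space of query length m and database size n."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    scheme = scheme or _DEFAULT_SCHEME
    bit_score = (scheme.lambda_ * raw_score - math.log(scheme.kappa)) / math.log(2.0)
    evalue = scheme.kappa * m * n * math.exp(-scheme.lambda_ * raw_score)
    if evalue == 0.0:  # guard against underflow; e-values stay positive
        evalue = 5e-324
    return bit_score, evalue


def _query_segments(
    read_seq: str, scheme: ScoringScheme
) -> list[tuple[int, int, int, np.ndarray]]:
    """All stop-free query segments over six frames, as tuples of
    (frame, frame_peptide_length, segment_offset, encoded_segment)."""
    out = []
    for frame, peptide in six_frame_translate(read_seq, scheme).items():
        for offset, segment in _stop_free_segments(peptide):
            out.append((frame, len(peptide), offset, encode_peptide(segment)))
    return out


def _candidate_subjects(
    segments: list[tuple[int, int, int, np.ndarray]],
    database: "CogDatabase",
    k: int,
) -> list[int]:
    """Heuristic-mode prefilter: subject indices sharing at least one
    k-peptide word with any query segment."""
    index = database.seed_index(k)
    candidates: set[int] = set()
    for _, _, _, enc in segments:
        for i in range(len(enc) - k + 1):
            word = bytes(enc[i : i + k].astype(np.uint8))
            candidates.update(index.get(word, ()))
    return sorted(candidates)


def search_read(
    read: "ReadRecord",
    database: "CogDatabase",
    config: Optional[SearchConfig] = None,
    scheme: Optional[ScoringScheme] = None,
) -> Optional[AlignmentHit]:
    """Best sub-threshold translated hit of a read against a database.

    Evaluates all six frames against every subject (exact mode) or
    against seed-sharing subjects (heuristic mode); returns the hit
    with the smallest e-value among those below the threshold, breaking
    ties by larger raw score then lexicographic subject id, or ``None``
    when nothing passes.
    """
    config = config or SearchConfig()
    scheme = scheme or _DEFAULT_SCHEME
    if len(database) == 0:
        raise ValueError("database is empty")
    if len(read.nt_sequence) < 3:
        logger.warning("read %s shorter than one codon; skipped", read.read_id)
        return None

    segments = _query_segments(read.nt_sequence, scheme)
    if not segments:
        return None
    n_db = database.total_residues()
    mat = scheme.substitution_matrix

    if config.engine_mode == "heuristic":
        subject_indices = _candidate_subjects(segments, database, config.seed_word_length)
    else:
        subject_indices = range(len(database.proteins))

    encoded = database.encoded_sequences()
    best_key = None
    best = None  # (subject, frame, m, offset, enc, score)
    for si in subject_indices:
        subject = database.proteins[si]
        s_enc = encoded[si]
        for frame, m, offset, q_enc in segments:
            _count_alignment_call()
            score = int(sw_score(q_enc, s_enc, mat, scheme.first_gap, scheme.gap_extend))
            if score <= 0:
                continue
            _, evalue = score_to_evalue(score, m, n_db, scheme)
            if evalue >= config.evalue_threshold:
                continue
            key = (evalue, -score, subject.protein_id, FRAMES.index(frame))
            if best_key is None or key < best_key:
                best_key = key
                best = (subject, frame, m, offset, q_enc, score)
    if best is None:
        return None

    subject, frame, m, offset, q_enc, score = best
    bit_score, evalue = score_to_evalue(score, m, n_db, scheme)
    _count_alignment_call()
    score2, qs, qe, ss, se, n_match, n_col = sw_align(
        q_enc,
        encode_peptide(subject.aa_sequence),
        mat,
        scheme.first_gap,
        scheme.gap_extend,
    )
    return AlignmentHit(
        query_id=read.read_id,
        subject_id=subject.protein_id,
        frame=frame,
        raw_score=score,
        bit_score=bit_score,
        evalue=evalue,
        q_aa_start=qs + offset,
        q_aa_end=qe + offset,
        s_start=ss,
        s_end=se,
        identity_fraction=(n_match / n_col) if n_col else 0.0,
    )


_DEFAULT_SCHEME = ScoringScheme()
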