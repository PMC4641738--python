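"""Synthetic fixture generator: a miniature COG-like protein database
with known family structure, a bijective cross-mapping truth table,
and reads of known provenance sampled from the proteins.

The generator emulates the role of a reference database plus
benchmark read sets: each of up to 25 functional categories carries a
few orthologous groups; each group's members derive from a random
ancestor protein by per-site substitution; reads are codon-exact
windows of member proteins, reverse-translated with uniformly random
synonymous codons, optionally corrupted by nucleotide substitution
errors and placed on either strand.  Everything is a pure function of
the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .cogdb import CATEGORY_CODES, CogDatabase, ProteinRecord
from .crossmap import CrossMap
from .io_formats import ReadRecord
from .translate_align import ScoringScheme, reverse_complement

#: 20 standard amino acids (no X) used for ancestor sequences
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults give a 25-category, 50-group, 150-protein database and
    150 nt error-free reads — small enough to search exhaustively,
    rich enough to exercise every pipeline stage.
    """

    n_categories: int = 25
    cogs_per_category: int = 2
    proteins_per_cog: int = 3
    protein_length: int = 120
    intra_cog_substitution_rate: float = 0.1
    n_reads: int = 100
    read_length_nt: int = 150
    nt_error_rate: float = 0.0
    revcomp_probability: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("intra_cog_substitution_rate", "nt_error_rate", "revcomp_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_categories", "cogs_per_category", "proteins_per_cog",
                     "protein_length", "n_reads", "read_length_nt"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_categories > len(CATEGORY_CODES):
            raise ValueError(f"n_categories must be <= {len(CATEGORY_CODES)}")


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    source_protein_id: str
    source_cog_id: str
    source_categories: frozenset[str]
    strand: str  # '+' or '-'
    nt_errors_introduced: int


def _mutate_protein(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution to a uniformly chosen different residue."""
    residues = list(ancestor)
    for i in range(len(residues)):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(residues[i], "")
            residues[i] = choices[rng.integers(len(choices))]
    return "".join(residues)


def generate_toy_cogdb(cfg: SimulationConfig) -> tuple[CogDatabase, CrossMap]:
    """Build the miniature tagged database and its truth cross-map.

    The cross-map is bijective per namespace (one synthetic KEGG,
    Pfam, GO and SEED term per group), so derived-annotation accuracy
    against truth equals COG accuracy by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins: list[ProteinRecord] = []
    entries: dict[str, dict[str, frozenset[str]]] = {}
    cog_index = 0
    protein_index = 0
    for cat in CATEGORY_CODES[: cfg.n_categories]:
        for _ in range(cfg.cogs_per_category):
            cog_index += 1
            cog_id = f"COG{cog_index:04d}"
            ancestor = "".join(
                AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=cfg.protein_length)
            )
            for _ in range(cfg.proteins_per_cog):
                protein_index += 1
                proteins.append(
                    ProteinRecord(
                        protein_id=f"P{protein_index:05d}",
                        aa_sequence=_mutate_protein(
                            ancestor, cfg.intra_cog_substitution_rate, rng
                        ),
                        cog_id=cog_id,
                        categories=frozenset({cat}),
                    )
                )
            entries[cog_id] = {
                "KEGG": frozenset({f"K{cog_index:05d}"}),
                "PFAM": frozenset({f"PF{cog_index:05d}"}),
                "GO": frozenset({f"GO:{cog_index:07d}"}),
                "SEED": frozenset({f"SEED:{cog_index:04d}"}),
            }
    return CogDatabase(proteins, kind="full"), CrossMap(entries=entries)


def _inverse_code(scheme: ScoringScheme) -> dict[str, list[str]]:
    inv: dict[str, list[str]] = {}
    for codon, aa in sorted(scheme.genetic_code.items()):
        inv.setdefault(aa, []).append(codon)
    return inv


def sample_reads(
    db: CogDatabase, cfg: SimulationConfig, scheme: Optional[ScoringScheme] = None
) -> tuple[list[ReadRecord], list[ReadTruth]]:
    """Sample reads of known provenance from database proteins.

    Each read picks a protein uniformly, takes a codon-aligned peptide
    window, reverse-translates it with uniform synonymous codons,
    applies i.i.d. substitution errors at ``nt_error_rate`` and lands
    on the reverse strand with ``revcomp_probability``.  Read lengths
    are rounded down to a whole number of codons.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    scheme = scheme or ScoringScheme()
    inv_code = _inverse_code(scheme)
    n_codons = cfg.read_length_nt // 3
    if n_codons < 1:
        raise ValueError("read_length_nt must cover at least one codon")
    too_short = [p.protein_id for p in db.proteins if len(p.aa_sequence) < n_codons]
    if too_short:
        raise ValueError(
            f"reads of {n_codons} codons exceed protein length for {too_short[:5]}"
        )
    rng = np.random.default_rng([cfg.seed, 1])
    reads: list[ReadRecord] = []
    truths: list[ReadTruth] = []
    for i in range(cfg.n_reads):
        protein = db.proteins[rng.integers(len(db.proteins))]
        start = int(rng.integers(len(protein.aa_sequence) - n_codons + 1))
        window = protein.aa_sequence[start : start + n_codons]
        codons = [
            inv_code[aa][rng.integers(len(inv_code[aa]))] if aa in inv_code else "NNN"
            for aa in window
        ]
        seq = list("".join(codons))
        n_errors = 0
        if cfg.nt_error_rate > 0:
            for j in range(len(seq)):
                if rng.random() < cfg.nt_error_rate:
                    seq[j] = BASES.replace(seq[j], "")[rng.integers(3)]
                    n_errors += 1
        nt = "".join(seq)
        strand = "+"
        if rng.random() < cfg.revcomp_probability:
            nt = reverse_complement(nt)
            strand = "-"
        read_id = f"R{i + 1:05d}"
        reads.append(ReadRecord(read_id=read_id, nt_sequence=nt))
        truths.append(
            ReadTruth(
                read_id=read_id,
                source_protein_id=protein.protein_id,
                source_cog_id=protein.cog_id,
                source_categories=protein.categories,
                strand=strand,
                nt_errors_introduced=n_errors,
            )
        )
    return reads, truths


def sample_category_reads(
    db: CogDatabase,
    cfg: SimulationConfig,
    reads_per_category: int,
    scheme: Optional[ScoringScheme] = None,
) -> tuple[list[ReadRecord], list[ReadTruth]]:
    """Sample a fixed number of reads from each category's proteins.

    Guarantees every category present in the database is represented;
    read ids are prefixed with the category code to stay unique.
    """
    reads: list[ReadRecord] = []
    truths: list[ReadTruth] = []
    for cat in sorted(db.by_category):
        sub = CogDatabase(db.by_category[cat], kind="full")
        cat_reads, cat_truths = sample_reads(
            sub, replace(cfg, n_reads=reads_per_category), scheme
        )
        for read, truth in zip(cat_reads, cat_truths):
            reads.append(replace(read, read_id=f"{cat}_{read.read_id}"))
            truths.append(replace(truth, read_id=f"{cat}_{truth.read_id}"))
    return reads, truths


def random_reads(n: int, length_nt: int = 150, seed: int = 7) -> list[ReadRecord]:
    """Reads of i.i.d. uniform bases — the unassignable negative class."""
    rng = np.random.default_rng([seed, 2])
    return [
        ReadRecord(
            read_id=f"RND{i + 1:05d}",
            nt_sequence="".join(BASES[b] for b in rng.integers(4, size=length_nt)),
        )
        for i in range(n)
    ]


def write_truth_table(truths: list[ReadTruth], path) -> None:
    """Serialize read provenance as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsource_protein_id\tsource_cog_id\tsource_categories"
            "\tstrand\tnt_errors_introduced\n"
        )
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.source_protein_id}\t{t.source_cog_id}\t"
                f"{''.join(sorted(t.source_categories))}\t{t.strand}\t"
                f"{t.nt_errors_introduced}\n"
            )
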