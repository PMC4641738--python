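"""The tagged protein reference database and its two derived forms.

A reference protein carries a COG (orthologous-group) id and one or
more of the 25 single-letter functional category codes.  Two database
transformations feed the directed-search workflow:

* ``build_reduced_db`` clusters each category's proteins greedily at a
  sequence-identity threshold and keeps the longest member of each
  cluster as a tagged representative ("customized" database);
* ``partition_by_category`` slices the full database into per-category
  subsets for the second search stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .translate_align import AA_ALPHABET, ScoringScheme, encode_peptide, local_align

PathLike = Union[str, Path]

#: the 25 single-letter functional category codes, in conventional order
CATEGORY_CODES = (
    "J", "A", "K", "L", "B", "D", "Y", "V", "T", "M", "N", "Z", "W",
    "U", "O", "C", "G", "E", "F", "H", "I", "P", "Q", "R", "S",
)
CATEGORY_SET = frozenset(CATEGORY_CODES)

_VALID_AA = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """A COG-tagged reference protein."""

    protein_id: str
    aa_sequence: str
    cog_id: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.aa_sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.aa_sequence) - _VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)}"
            )
        if not self.categories:
            raise ValueError(f"protein {self.protein_id}: no categories")
        unknown = set(self.categories) - CATEGORY_SET
        if unknown:
            raise ValueError(
                f"protein {self.protein_id}: unknown categories {sorted(unknown)}"
            )


@dataclass(frozen=True)
class Cluster:
    """One identity cluster within a single category context."""

    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


class CogDatabase:
    """In-memory protein database with category and COG indexes.

    ``kind`` is "full" for a source database and "reduced" for a
    clustered representative database, in which case ``provenance``
    maps each representative record id to the member protein ids of
    its cluster.
    """

    def __init__(
        self,
        proteins: Iterable[ProteinRecord],
        kind: str = "full",
        provenance: Optional[dict[str, tuple[str, ...]]] = None,
    ) -> None:
        if kind not in ("full", "reduced"):
            raise ValueError(f"kind must be full or reduced, got {kind!r}")
        self.proteins: list[ProteinRecord] = list(proteins)
        self.kind = kind
        self.provenance = provenance
        self.by_id: dict[str, ProteinRecord] = {}
        self.by_category: dict[str, list[ProteinRecord]] = {}
        self.by_cog: dict[str, list[ProteinRecord]] = {}
        for p in self.proteins:
            if p.protein_id in self.by_id:
                raise ValueError(f"duplicate protein_id {p.protein_id!r}")
            self.by_id[p.protein_id] = p
            for cat in p.categories:
                self.by_category.setdefault(cat, []).append(p)
            self.by_cog.setdefault(p.cog_id, []).append(p)
        self._encoded: Optional[list[np.ndarray]] = None
        self._seed_indexes: dict[int, dict[bytes, set[int]]] = {}

    def __len__(self) -> int:
        return len(self.proteins)

    def total_residues(self) -> int:
        return sum(len(p.aa_sequence) for p in self.proteins)

    def encoded_sequences(self) -> list[np.ndarray]:
        """Matrix-index encodings of all subject sequences (cached)."""
        if self._encoded is None:
            self._encoded = [encode_peptide(p.aa_sequence) for p in self.proteins]
        return self._encoded

    def seed_index(self, k: int) -> dict[bytes, set[int]]:
        """k-peptide word -> subject indices, for the heuristic engine."""
        if k not in self._seed_indexes:
            index: dict[bytes, set[int]] = {}
            for si, enc in enumerate(self.encoded_sequences()):
                u8 = enc.astype(np.uint8)
                for i in range(len(u8) - k + 1):
                    index.setdefault(bytes(u8[i : i + k]), set()).add(si)
            self._seed_indexes[k] = index
        return self._seed_indexes[k]


def _cluster_identity(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> float:
    """CD-HIT-style identity: matched columns of the best local
    alignment divided by the shorter sequence length."""
    aln = local_align(a.aa_sequence, b.aa_sequence, scheme)
    return aln.n_matches / min(len(a.aa_sequence), len(b.aa_sequence))


def cluster_category(
    proteins: Iterable[ProteinRecord],
    identity_threshold: float = 0.6,
    scheme: Optional[ScoringScheme] = None,
) -> list[Cluster]:
    """Greedy incremental identity clustering of one category's proteins.

    Proteins are visited in decreasing length (ties: lexicographic id);
    each joins the first existing cluster whose founding representative
    it matches at >= identity_threshold, else founds a new cluster.
    The final representative is the longest member (ties: smallest id).
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    scheme = scheme or ScoringScheme()
    ordered = sorted(proteins, key=lambda p: (-len(p.aa_sequence), p.protein_id))
    founders: list[ProteinRecord] = []
    members: list[list[ProteinRecord]] = []
    for p in ordered:
        for ci, founder in enumerate(founders):
            if _cluster_identity(p, founder, scheme) >= identity_threshold:
                members[ci].append(p)
                break
        else:
            founders.append(p)
            members.append([p])
    clusters = []
    for group in members:
        rep = min(group, key=lambda p: (-len(p.aa_sequence), p.protein_id))
        clusters.append(
            Cluster(
                member_ids=frozenset(p.protein_id for p in group),
                representative_id=rep.protein_id,
            )
        )
    return clusters


def reduced_record_id(representative_id: str, category: str) -> str:
    """Id of a representative record in the reduced database; the
    category suffix keeps multi-category representatives distinct."""
    return f"{representative_id}__{category}"


def build_reduced_db(
    full: CogDatabase,
    identity_threshold: float = 0.6,
    scheme: Optional[ScoringScheme] = None,
) -> CogDatabase:
    """Cluster each category independently and pool the longest-member
    representatives into the reduced ("customized") database.

    Each representative record is tagged with the single category it
    was clustered under; provenance maps its record id to the member
    protein ids of its cluster.
    """
    if full.kind != "full":
        raise ValueError("input database must have kind='full'")
    scheme = scheme or ScoringScheme()
    reduced: list[ProteinRecord] = []
    provenance: dict[str, tuple[str, ...]] = {}
    for category in CATEGORY_CODES:
        cat_proteins = full.by_category.get(category)
        if not cat_proteins:
            continue
        for cluster in cluster_category(cat_proteins, identity_threshold, scheme):
            rep = full.by_id[cluster.representative_id]
            rec_id = reduced_record_id(rep.protein_id, category)
            reduced.append(
                ProteinRecord(
                    protein_id=rec_id,
                    aa_sequence=rep.aa_sequence,
                    cog_id=rep.cog_id,
                    categories=frozenset({category}),
                )
            )
            provenance[rec_id] = tuple(sorted(cluster.member_ids))
    return CogDatabase(reduced, kind="reduced", provenance=provenance)


def partition_by_category(full: CogDatabase) -> dict[str, list[ProteinRecord]]:
    """Per-category slices of the database; a protein tagged with k
    categories appears in k partitions."""
    return {cat: list(ps) for cat, ps in full.by_category.items()}


# -- tagged-FASTA persistence -------------------------------------------------
# header dialect: >protein_id|cog_id|CATEGORIES  (e.g. >P0001|COG0443|O)

def load_cog_fasta(
    path: PathLike, kind: str = "full", provenance_path: Optional[PathLike] = None
) -> CogDatabase:
    """Load a tagged-FASTA protein database."""
    path = Path(path)
    proteins = []
    with open(path) as fh:
        for n, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            parts = title.split()[0].split("|")
            if len(parts) != 3 or not all(parts):
                raise ValueError(
                    f"{path}: record {n}: header must be "
                    f"'protein_id|cog_id|CATEGORIES', got {title!r}"
                )
            proteins.append(
                ProteinRecord(
                    protein_id=parts[0],
                    aa_sequence=seq.upper(),
                    cog_id=parts[1],
                    categories=frozenset(parts[2]),
                )
            )
    provenance = None
    if provenance_path is not None:
        provenance = {}
        with open(provenance_path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "representative_id":
                    continue
                provenance.setdefault(row[0], []).append(row[1])
        provenance = {k: tuple(v) for k, v in provenance.items()}
    return CogDatabase(proteins, kind=kind, provenance=provenance)


def write_cog_fasta(db: CogDatabase, path: PathLike, width: int = 70) -> None:
    """Write a database as tagged FASTA."""
    with open(path, "w") as fh:
        for p in db.proteins:
            fh.write(f">{p.protein_id}|{p.cog_id}|{''.join(sorted(p.categories))}\n")
            for i in range(0, len(p.aa_sequence), width):
                fh.write(p.aa_sequence[i : i + width] + "\n")


def write_provenance(db: CogDatabase, path: PathLike) -> None:
    """Write a reduced database's cluster membership as TSV."""
    if db.provenance is None:
        raise ValueError("database has no provenance to write")
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\n")
        for rep_id in sorted(db.provenance):
            for member in db.provenance[rep_id]:
                fh.write(f"{rep_id}\t{member}\n")
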