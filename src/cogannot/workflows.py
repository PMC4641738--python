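"""The four annotation workflows.

Options 1 and 2 are single-pass: every read is searched against the
full database (option 1 with the exact engine, option 2 with the
seeded heuristic engine) and assigned the COG of its best
sub-threshold hit.  Options 3 and 4 are the directed two-stage
variants: stage 1 searches the reduced representative database to
assign a tentative category, stage 2 searches only that category's
slice of the full database.  All options share the same mapping phase
(cross-map lookup) and feed the same profile builder.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .cogdb import CogDatabase, ProteinRecord, partition_by_category
from .crossmap import CrossMap, transfer_annotations
from .io_formats import ExternalHitRow, ReadRecord
from .records import AnnotationRecord, CogAssignment, NAMESPACE_ORDER
from .translate_align import AlignmentHit, ScoringScheme, SearchConfig, search_read

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: engine mode used by each workflow option
OPTION_ENGINE = {1: "exact", 2: "heuristic", 3: "exact", 4: "heuristic"}


@dataclass
class FunctionalProfile:
    """Per-namespace term counts over a read set (multi-label: a read
    with k terms in a namespace increments k counters)."""

    counts: dict[str, Counter] = field(default_factory=dict)
    n_reads_total: int = 0
    n_reads_assigned: dict[str, int] = field(default_factory=dict)

    def namespace_counts(self, namespace: str) -> Counter:
        return self.counts.get(namespace, Counter())


def build_profile(records: Iterable[AnnotationRecord]) -> FunctionalProfile:
    """Aggregate annotation records into a functional profile."""
    profile = FunctionalProfile(
        counts={ns: Counter() for ns in NAMESPACE_ORDER},
        n_reads_assigned={ns: 0 for ns in NAMESPACE_ORDER},
    )
    for rec in records:
        profile.n_reads_total += 1
        for ns in NAMESPACE_ORDER:
            terms = rec.get(ns)
            if terms:
                profile.n_reads_assigned[ns] += 1
                for term in terms:
                    profile.counts[ns][term] += 1
    return profile


def _assignment_from_hit(
    read_id: str,
    hit: Optional[AlignmentHit],
    db: CogDatabase,
    option: int,
    stage1_category: Optional[str] = None,
) -> CogAssignment:
    if hit is None:
        return CogAssignment(read_id=read_id, option=option, stage1_category=stage1_category)
    protein = db.by_id[hit.subject_id]
    return CogAssignment(
        read_id=read_id,
        cog_id=protein.cog_id,
        categories=protein.categories,
        best_hit=hit,
        option=option,
        stage1_category=stage1_category,
    )


def _best_external_hit(
    rows: Sequence[ExternalHitRow], threshold: float
) -> dict[str, ExternalHitRow]:
    """Best sub-threshold row per query: smallest e-value, then larger
    bit score, then lexicographic subject id."""
    best: dict[str, ExternalHitRow] = {}
    for row in rows:
        if row.evalue >= threshold:
            continue
        cur = best.get(row.query_id)
        key = (row.evalue, -row.bit_score, row.subject_id)
        if cur is None or key < (cur.evalue, -cur.bit_score, cur.subject_id):
            best[row.query_id] = row
    return best


def directed_assign(
    read: ReadRecord,
    reduced_db: CogDatabase,
    partitions: dict[str, list[ProteinRecord]],
    config: Optional[SearchConfig] = None,
    scheme: Optional[ScoringScheme] = None,
    option: int = 3,
    full_db: Optional[CogDatabase] = None,
    fallback_full: bool = False,
    _partition_dbs: Optional[dict[frozenset, CogDatabase]] = None,
) -> CogAssignment:
    """Two-stage directed assignment of a single read.

    Stage 1: best sub-threshold hit against the reduced database fixes
    the tentative category (the winning representative's tag).  Stage
    2: best sub-threshold hit against the union of the winner's
    category partitions of the full database fixes the final COG.  A
    stage-1 miss leaves the read unassigned; a stage-2 miss records
    the tentative category and (optionally, off by default) falls back
    to a full-database search.
    """
    if not partitions:
        raise ValueError("partitions map is empty")
    config = config or SearchConfig()
    scheme = scheme or ScoringScheme()

    stage1_hit = search_read(read, reduced_db, config, scheme)
    if stage1_hit is None:
        return CogAssignment(read_id=read.read_id, option=option)
    winner = reduced_db.by_id[stage1_hit.subject_id]
    stage1_cats = frozenset(winner.categories)
    stage1_category = min(stage1_cats)

    if _partition_dbs is None:
        _partition_dbs = {}
    if stage1_cats not in _partition_dbs:
        pooled: dict[str, ProteinRecord] = {}
        for cat in sorted(stage1_cats):
            for p in partitions.get(cat, ()):
                pooled[p.protein_id] = p
        _partition_dbs[stage1_cats] = CogDatabase(pooled.values(), kind="full")
    stage2_db = _partition_dbs[stage1_cats]

    stage2_hit = search_read(read, stage2_db, config, scheme) if len(stage2_db) else None
    if stage2_hit is None and fallback_full and full_db is not None:
        stage2_hit = search_read(read, full_db, config, scheme)
        if stage2_hit is not None:
            return _assignment_from_hit(
                read.read_id, stage2_hit, full_db, option, stage1_category
            )
    return _assignment_from_hit(
        read.read_id, stage2_hit, stage2_db, option, stage1_category
    )


def run_option(
    reads: Sequence[ReadRecord],
    full_db: CogDatabase,
    reduced_db: Optional[CogDatabase],
    xmap: CrossMap,
    option: int,
    config: Optional[SearchConfig] = None,
    scheme: Optional[ScoringScheme] = None,
    external_hits: Optional[Sequence[ExternalHitRow]] = None,
    fallback_full: bool = False,
) -> tuple[list[AnnotationRecord], list[CogAssignment]]:
    """Run one workflow option end to end over a read set.

    Returns one AnnotationRecord per read, in input order, plus the
    underlying COG assignments.  Options 3/4 require ``reduced_db``.
    Pre-computed external hits (options 1/2) replace the built-in
    search when supplied.
    """
    if option not in (1, 2, 3, 4):
        raise ValueError(f"option must be 1-4, got {option}")
    if option in (3, 4) and reduced_db is None:
        raise ValueError(f"option {option} requires a reduced database")
    scheme = scheme or ScoringScheme()
    if config is None:
        config = SearchConfig(engine_mode=OPTION_ENGINE[option])
    elif config.engine_mode != "external":
        config = SearchConfig(
            evalue_threshold=config.evalue_threshold,
            engine_mode=OPTION_ENGINE[option],
            seed_word_length=config.seed_word_length,
            max_hits_retained=config.max_hits_retained,
        )

    assignments: list[CogAssignment] = []
    if external_hits is not None:
        if option in (3, 4):
            raise ValueError("external hits apply to single-pass options 1/2 only")
        best = _best_external_hit(external_hits, config.evalue_threshold)
        unknown = {r.subject_id for r in best.values()} - set(full_db.by_id)
        if unknown:
            raise ValueError(f"external hits reference unknown subjects {sorted(unknown)}")
        for read in reads:
            row = best.get(read.read_id)
            hit = None
            if row is not None:
                hit = AlignmentHit(
                    query_id=row.query_id,
                    subject_id=row.subject_id,
                    frame=1,
                    raw_score=0,
                    bit_score=row.bit_score,
                    evalue=row.evalue,
                    q_aa_start=min(row.q_start, row.q_end),
                    q_aa_end=max(row.q_start, row.q_end),
                    s_start=min(row.s_start, row.s_end),
                    s_end=max(row.s_start, row.s_end),
                    identity_fraction=row.percent_identity / 100.0,
                )
            assignments.append(_assignment_from_hit(read.read_id, hit, full_db, option))
    elif option in (1, 2):
        for read in reads:
            hit = search_read(read, full_db, config, scheme)
            assignments.append(_assignment_from_hit(read.read_id, hit, full_db, option))
    else:
        partitions = partition_by_category(full_db)
        partition_dbs: dict[frozenset, CogDatabase] = {}
        for read in reads:
            assignments.append(
                directed_assign(
                    read,
                    reduced_db,
                    partitions,
                    config,
                    scheme,
                    option=option,
                    full_db=full_db,
                    fallback_full=fallback_full,
                    _partition_dbs=partition_dbs,
                )
            )

    records = [transfer_annotations(a, xmap) for a in assignments]
    n_assigned = sum(a.assigned for a in assignments)
    logger.info(
        "option %d: %d/%d reads assigned a COG", option, n_assigned, len(assignments)
    )
    return records, assignments


# -- profile persistence ------------------------------------------------------

def write_profile(profile: FunctionalProfile, path: PathLike) -> None:
    """Serialize a functional profile as TSV."""
    with open(path, "w") as fh:
        fh.write(f"# n_reads_total\t{profile.n_reads_total}\n")
        for ns in NAMESPACE_ORDER:
            fh.write(f"# n_reads_assigned\t{ns}\t{profile.n_reads_assigned.get(ns, 0)}\n")
        fh.write("namespace\tterm\tcount\n")
        for ns in NAMESPACE_ORDER:
            for term in sorted(profile.namespace_counts(ns)):
                fh.write(f"{ns}\t{term}\t{profile.counts[ns][term]}\n")


def read_profile(path: PathLike) -> FunctionalProfile:
    """Companion reader for write_profile."""
    profile = FunctionalProfile(
        counts={ns: Counter() for ns in NAMESPACE_ORDER},
        n_reads_assigned={ns: 0 for ns in NAMESPACE_ORDER},
    )
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("namespace\t"):
                continue
            if line.startswith("# n_reads_total"):
                profile.n_reads_total = int(line.split("\t")[1])
            elif line.startswith("# n_reads_assigned"):
                _, ns, n = line.split("\t")
                profile.n_reads_assigned[ns] = int(n)
            else:
                ns, term, count = line.split("\t")
                profile.counts[ns][term] = int(count)
    return profile
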