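"""Workflow orchestration: single-pass and directed options, the
shared mapping phase, and profile construction."""

import pytest

from cogannot import translate_align
from cogannot.cogdb import CogDatabase, partition_by_category
from cogannot.crossmap import CrossMap
from cogannot.io_formats import ExternalHitRow, ReadRecord
from cogannot.records import AnnotationRecord
from cogannot.synthetic import random_reads
from cogannot.translate_align import SearchConfig, search_read
from cogannot.workflows import build_profile, directed_assign, run_option


def test_option1_planted_reads_recover_truth(small_fixture):
    db, xmap, reads, truths = small_fixture
    records, assignments = run_option(reads, db, None, xmap, option=1)
    assert len(records) == len(reads)
    for rec, asg, truth in zip(records, assignments, truths):
        assert rec.read_id == truth.read_id
        assert asg.cog_id == truth.source_cog_id
        assert rec.get("COG") == {truth.source_cog_id}
        assert rec.get("CATEGORY") == truth.source_categories
        # bijective truth cross-map: derived terms follow the COG
        assert rec.get("KEGG") == xmap.terms(truth.source_cog_id, "KEGG")
        assert rec.get("SEED") == xmap.terms(truth.source_cog_id, "SEED")


def test_option1_equals_direct_benchmark_search(small_fixture):
    """Option 1 and the benchmark procedure (direct full-database
    search with the same engine and threshold) give identical COG
    labels for every read."""
    db, xmap, reads, _ = small_fixture
    _, assignments = run_option(reads, db, None, xmap, option=1)
    config = SearchConfig(engine_mode="exact")
    for read, asg in zip(reads, assignments):
        hit = search_read(read, db, config)
        if hit is None:
            assert not asg.assigned
        else:
            assert asg.cog_id == db.by_id[hit.subject_id].cog_id


def test_unassigned_read_yields_empty_record(small_fixture):
    db, xmap, _, _ = small_fixture
    reads = random_reads(3, seed=13)
    records, assignments = run_option(reads, db, None, xmap, option=1)
    assert all(not a.assigned for a in assignments)
    assert all(not r.annotated for r in records)


def test_option3_requires_reduced_db(small_fixture):
    db, xmap, reads, _ = small_fixture
    with pytest.raises(ValueError):
        run_option(reads[:1], db, None, xmap, option=3)


def test_directed_two_stage_recovers_planted(small_fixture, small_reduced):
    db, xmap, reads, truths = small_fixture
    records, assignments = run_option(reads, db, small_reduced, xmap, option=3)
    for asg, truth in zip(assignments, truths):
        assert asg.stage1_category is not None
        assert asg.cog_id == truth.source_cog_id


def test_directed_random_read_unassigned(small_fixture, small_reduced):
    db, _, _, _ = small_fixture
    partitions = partition_by_category(db)
    (read,) = random_reads(1, seed=3)
    asg = directed_assign(read, small_reduced, partitions)
    assert not asg.assigned
    assert asg.stage1_category is None


def test_directed_empty_partitions_rejected(small_fixture, small_reduced):
    _, _, reads, _ = small_fixture
    with pytest.raises(ValueError):
        directed_assign(reads[0], small_reduced, {})


def test_conditional_option_equivalence(small_fixture, small_reduced):
    """Whenever option 1's best-hit protein shares a category with the
    stage-1 winner's tags, option 3 assigns the same COG."""
    db, xmap, reads, _ = small_fixture
    _, asg1 = run_option(reads, db, None, xmap, option=1)
    _, asg3 = run_option(reads, db, small_reduced, xmap, option=3)
    checked = 0
    for a1, a3 in zip(asg1, asg3):
        if a1.assigned and a3.stage1_category is not None:
            if a3.stage1_category in a1.categories:
                assert a3.cog_id == a1.cog_id
                checked += 1
    assert checked > 0


def test_stage2_search_space_is_strict_subset(small_fixture, small_reduced):
    """Stage 2 of the directed search touches only the stage-1
    category's slice of the full database."""
    db, _, reads, truths = small_fixture
    partitions = partition_by_category(db)
    asg = directed_assign(reads[0], small_reduced, partitions)
    assert asg.assigned
    cat_ids = {p.protein_id for p in partitions[asg.stage1_category]}
    assert asg.best_hit.subject_id in cat_ids
    assert len(cat_ids) < len(db)


def test_mapping_phase_uniform_across_options(small_fixture, small_reduced):
    """For reads where two options agree on the COG, the derived
    namespaces agree too (the mapping phase is option-independent)."""
    db, xmap, reads, _ = small_fixture
    rec1, asg1 = run_option(reads, db, None, xmap, option=1)
    rec4, asg4 = run_option(reads, db, small_reduced, xmap, option=4)
    agreeing = 0
    for r1, r4, a1, a4 in zip(rec1, rec4, asg1, asg4):
        if a1.cog_id == a4.cog_id:
            for ns in ("KEGG", "PFAM", "GO", "SEED"):
                assert r1.get(ns) == r4.get(ns)
            agreeing += 1
    assert agreeing > 0


def test_external_hits_drive_option1(small_fixture):
    """Pre-computed tabular hits replace the built-in engine: COG
    labels follow the rows and no alignment is computed."""
    db, xmap, reads, truths = small_fixture
    rows = [
        ExternalHitRow(
            query_id=t.read_id,
            subject_id=t.source_protein_id,
            percent_identity=100.0,
            alignment_length=50,
            mismatches=0,
            gap_opens=0,
            q_start=1,
            q_end=150,
            s_start=1,
            s_end=50,
            evalue=1e-30,
            bit_score=100.0,
        )
        for t in truths[:10]
    ]
    translate_align.reset_alignment_call_count()
    records, assignments = run_option(
        reads[:10], db, None, xmap, option=1,
        config=SearchConfig(engine_mode="external"), external_hits=rows,
    )
    assert translate_align.alignment_call_count() == 0
    for asg, t in zip(assignments, truths[:10]):
        assert asg.cog_id == t.source_cog_id


def test_external_hits_unknown_subject_rejected(small_fixture):
    db, xmap, reads, _ = small_fixture
    rows = [
        ExternalHitRow(reads[0].read_id, "nonexistent", 100.0, 50, 0, 0,
                       1, 150, 1, 50, 1e-30, 100.0)
    ]
    with pytest.raises(ValueError, match="nonexistent"):
        run_option(reads[:1], db, None, xmap, option=1,
                   config=SearchConfig(engine_mode="external"), external_hits=rows)


def test_build_profile_counts():
    recs = [
        AnnotationRecord("r1", {"KEGG": frozenset({"K00001"})}),
        AnnotationRecord("r2", {"KEGG": frozenset({"K00001"})}),
        AnnotationRecord("r3", {"KEGG": frozenset({"K00002"})}),
        AnnotationRecord("r4", {"GO": frozenset({"GO:1", "GO:2"})}),
        AnnotationRecord("r5", {}),
    ]
    profile = build_profile(recs)
    assert profile.namespace_counts("KEGG") == {"K00001": 2, "K00002": 1}
    assert profile.namespace_counts("GO") == {"GO:1": 1, "GO:2": 1}
    assert profile.n_reads_total == 5
    assert profile.n_reads_assigned["KEGG"] == 3
    assert profile.n_reads_assigned["GO"] == 1


def test_build_profile_empty():
    profile = build_profile([])
    assert profile.n_reads_total == 0
    assert profile.namespace_counts("KEGG") == {}
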