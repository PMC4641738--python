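"""The cross-mapping store: one COG call fans out into KEGG, Pfam, GO
and SEED terms.

Mapping rows come from two source classes — ``curated_import`` (mined
reference tables) and ``homology`` (sequence-search-derived).  When the
two classes disagree on a (COG, namespace) term set, the homology set
wins wholesale and the conflict is logged.  GO terms are additionally
derived by composing the COG->Pfam map with a Pfam->GO table
(pfam2go-style) and merged with any directly supplied GO rows; no
ontology-ancestor propagation is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .records import AnnotationRecord, CogAssignment, DERIVED_NAMESPACES

PathLike = Union[str, Path]

SOURCES = ("curated_import", "homology")


@dataclass(frozen=True)
class MappingSourceRow:
    """One (COG, namespace, term) assertion from one source class."""

    cog_id: str
    namespace: str
    term_id: str
    source: str

    def __post_init__(self) -> None:
        if not self.cog_id or not self.term_id:
            raise ValueError("cog_id and term_id must be non-empty")
        if self.namespace not in DERIVED_NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class Conflict:
    cog_id: str
    namespace: str
    discarded: frozenset[str]
    kept: frozenset[str]


@dataclass
class CrossMap:
    """Unified per-COG term sets in the four derived namespaces."""

    entries: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    conflict_log: list[Conflict] = field(default_factory=list)

    def terms(self, cog_id: str, namespace: str) -> frozenset[str]:
        return self.entries.get(cog_id, {}).get(namespace, frozenset())

    def __contains__(self, cog_id: str) -> bool:
        return cog_id in self.entries


def build_crossmap(
    rows: Iterable[MappingSourceRow],
    pfam2go: Iterable[tuple[str, str]] = (),
) -> CrossMap:
    """Collate source rows into a unified cross-map.

    Per (COG, namespace): if both source classes contribute and their
    term sets differ, the homology set is kept and the conflict logged;
    otherwise the union is kept.  GO sets then gain the composition of
    the kept Pfam set through the pfam2go pairs.  The result is
    independent of row order.
    """
    by_key: dict[tuple[str, str], dict[str, set[str]]] = {}
    for row in rows:
        slot = by_key.setdefault((row.cog_id, row.namespace), {s: set() for s in SOURCES})
        slot[row.source].add(row.term_id)

    entries: dict[str, dict[str, frozenset[str]]] = {}
    conflicts: list[Conflict] = []
    for (cog_id, namespace) in sorted(by_key):
        slot = by_key[(cog_id, namespace)]
        curated, homology = slot["curated_import"], slot["homology"]
        if curated and homology and curated != homology:
            kept = frozenset(homology)
            conflicts.append(
                Conflict(cog_id, namespace, frozenset(curated - homology), kept)
            )
        else:
            kept = frozenset(curated | homology)
        entries.setdefault(cog_id, {})[namespace] = kept

    go_by_pfam: dict[str, set[str]] = {}
    for pfam_id, go_id in pfam2go:
        go_by_pfam.setdefault(pfam_id, set()).add(go_id)
    for cog_id, namespaces in entries.items():
        composed = set()
        for pfam_id in namespaces.get("PFAM", frozenset()):
            composed.update(go_by_pfam.get(pfam_id, ()))
        if composed:
            namespaces["GO"] = namespaces.get("GO", frozenset()) | composed
    return CrossMap(entries=entries, conflict_log=conflicts)


def transfer_annotations(assignment: CogAssignment, xmap: CrossMap) -> AnnotationRecord:
    """Pure-lookup mapping phase: expand a COG call into all namespaces.

    Unassigned reads yield an all-empty record; a COG absent from the
    cross-map keeps its COG/category labels with the derived namespaces
    empty.  No alignment work happens here.
    """
    if not assignment.assigned:
        return AnnotationRecord(read_id=assignment.read_id, labels={})
    labels: dict[str, frozenset[str]] = {
        "COG": frozenset({assignment.cog_id}),
        "CATEGORY": frozenset(assignment.categories),
    }
    for namespace in DERIVED_NAMESPACES:
        labels[namespace] = xmap.terms(assignment.cog_id, namespace)
    return AnnotationRecord(read_id=assignment.read_id, labels=labels)


# -- persistence --------------------------------------------------------------

def read_mapping_rows(path: PathLike) -> list[MappingSourceRow]:
    """Read a mapping-source TSV (cog_id, namespace, term_id, source)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cog_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            rows.append(MappingSourceRow(*fields))
    return rows


_PFAM2GO_RE = re.compile(r"^Pfam:(\S+).*>\s*GO:.*;\s*(GO:\d+)\s*$")


def read_pfam2go(path: PathLike) -> list[tuple[str, str]]:
    """Parse the GO-site external2go flat-file dialect, e.g.
    ``Pfam:PF00001 7tm_1 > GO:signaling receptor activity ; GO:0038023``."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            m = _PFAM2GO_RE.match(line)
            if m is None:
                raise ValueError(f"{path}: line {lineno}: unparsable pfam2go line")
            pairs.append((m.group(1), m.group(2)))
    return pairs


def write_crossmap(xmap: CrossMap, path: PathLike) -> None:
    """Serialize the unified store as TSV (cog_id, namespace, term_id).

    The conflict log is a build-time artifact and is not serialized.
    """
    with open(path, "w") as fh:
        fh.write("cog_id\tnamespace\tterm_id\n")
        for cog_id in sorted(xmap.entries):
            for namespace in DERIVED_NAMESPACES:
                for term in sorted(xmap.terms(cog_id, namespace)):
                    fh.write(f"{cog_id}\t{namespace}\t{term}\n")


def read_crossmap(path: PathLike) -> CrossMap:
    """Load a serialized unified store; round-trips write_crossmap."""
    path = Path(path)
    entries: dict[str, dict[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cog_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            cog_id, namespace, term = fields
            if namespace not in DERIVED_NAMESPACES:
                raise ValueError(f"{path}: line {lineno}: unknown namespace")
            ns_map = entries.setdefault(cog_id, {})
            ns_map[namespace] = ns_map.get(namespace, frozenset()) | {term}
    return CrossMap(entries=entries)
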