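"""Shared record types for the annotation pipeline: a read's COG call
and the multi-namespace annotation row derived from it."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .translate_align import AlignmentHit

#: the five derivable namespaces plus the COG call itself, in output order
NAMESPACE_ORDER = ("COG", "CATEGORY", "KEGG", "PFAM", "GO", "SEED")
DERIVED_NAMESPACES = ("KEGG", "PFAM", "GO", "SEED")


@dataclass(frozen=True)
class CogAssignment:
    """A read's COG call with provenance.

    ``categories`` carries the full category set of the assigned
    protein (a multi-category protein keeps all its letters).  For the
    directed (two-stage) options, ``stage1_category`` records the tag
    of the stage-1 winning representative even when stage 2 misses.
    """

    read_id: str
    cog_id: Optional[str] = None
    categories: Optional[frozenset[str]] = None
    best_hit: Optional[AlignmentHit] = None
    option: int = 1
    stage1_category: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.cog_id is None) != (self.best_hit is None):
            raise ValueError("cog_id and best_hit must be both set or both unset")
        if self.cog_id is not None and not self.categories:
            raise ValueError("an assigned read must carry categories")
        if self.option not in (1, 2, 3, 4):
            raise ValueError(f"option must be 1-4, got {self.option}")

    @property
    def assigned(self) -> bool:
        return self.cog_id is not None


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-read term sets in each namespace; empty sets mean
    unannotated in that namespace.  The COG set has at most one member."""

    read_id: str
    labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(NAMESPACE_ORDER)
        if unknown:
            raise ValueError(f"unknown namespaces {sorted(unknown)}")
        if len(self.labels.get("COG", frozenset())) > 1:
            raise ValueError(f"read {self.read_id}: more than one COG label")

    def get(self, namespace: str) -> frozenset[str]:
        return self.labels.get(namespace, frozenset())

    @property
    def annotated(self) -> bool:
        return any(self.labels.get(ns) for ns in NAMESPACE_ORDER)
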