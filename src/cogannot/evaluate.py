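"""Validation harness: per-namespace confusion counting against a
benchmark annotation set, the PPV/NPV accuracy metrics, and Pearson
correlation between functional profiles.

Read-level confusion convention (multi-label namespaces): a read is a
true positive when the tool and benchmark term sets intersect, a false
positive when the tool labels but the benchmark is empty or disjoint,
a true negative when both are empty, and a false negative when only
the benchmark labels.  A stricter set-equality convention is available
behind ``strict=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .records import AnnotationRecord
from .workflows import FunctionalProfile

#: marker for PPV/NPV with an empty denominator (neither 0 nor 1, so
#: averages are never silently biased)
UNDEFINED = None


@dataclass(frozen=True)
class ConfusionCounts:
    namespace: str
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(
    tool: Iterable[AnnotationRecord],
    benchmark: Iterable[AnnotationRecord],
    namespace: str,
    strict: bool = False,
) -> ConfusionCounts:
    """Read-level confusion of a tool annotation against a benchmark.

    Both collections must cover exactly the same read ids.  With
    ``strict`` a true positive requires set equality instead of a
    non-empty intersection.
    """
    tool_by_id = {r.read_id: r.get(namespace) for r in tool}
    bench_by_id = {r.read_id: r.get(namespace) for r in benchmark}
    if set(tool_by_id) != set(bench_by_id):
        diff = sorted(set(tool_by_id) ^ set(bench_by_id))
        raise ValueError(f"read id sets differ; symmetric difference: {diff}")
    tp = fp = tn = fn = 0
    for read_id, tool_terms in tool_by_id.items():
        bench_terms = bench_by_id[read_id]
        if tool_terms:
            if strict:
                hit = tool_terms == bench_terms
            else:
                hit = bool(tool_terms & bench_terms)
            if hit:
                tp += 1
            else:
                fp += 1
        elif bench_terms:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(namespace=namespace, TP=tp, FP=fp, TN=tn, FN=fn)


def predictive_values(c: ConfusionCounts) -> tuple[Optional[float], Optional[float]]:
    """PPV = TP/(TP+FP) and NPV = TN/(TN+FN); an empty denominator
    yields the UNDEFINED marker rather than an exception."""
    ppv = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else UNDEFINED
    npv = c.TN / (c.TN + c.FN) if (c.TN + c.FN) > 0 else UNDEFINED
    return ppv, npv


def profile_correlation(
    a: FunctionalProfile, b: FunctionalProfile, namespace: str
) -> tuple[float, float]:
    """Pearson correlation between two profiles over one namespace.

    Count vectors are built over the union of the two term sets
    (absent terms count 0); the p-value is the two-sided t-test for r
    with n-2 degrees of freedom.
    """
    ca = a.namespace_counts(namespace)
    cb = b.namespace_counts(namespace)
    terms = sorted(set(ca) | set(cb))
    if len(terms) < 3:
        raise ValueError(
            f"need at least 3 terms in the union, got {len(terms)} for {namespace}"
        )
    va = np.array([ca.get(t, 0) for t in terms], dtype=float)
    vb = np.array([cb.get(t, 0) for t in terms], dtype=float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in a profile vector")
    result = stats.pearsonr(va, vb)
    return float(result.statistic), float(result.pvalue)
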