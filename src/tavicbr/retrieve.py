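"""Case retrieval: hierarchical CDT-driven retrieval and plain k-NN ranking.

The hierarchical measure walks the CDT level by level.  At level ``l`` it
scores the surviving cases with the weighted dissimilarity over the
cumulative attribute set of levels 1..l (level-decay weights), then — while
the guard ``m / 2**l > min_cases`` holds and ``l`` is not the last level —
keeps only the more similar half of the survivors (``ceil(count/2)``,
deterministic (dissimilarity, case id) order).  The final ranking and the
hierarchical similarity ``1 - diss_L`` are computed over the last surviving
set.  ``m`` in the guard is the size of the *initial* case-base, so the
filtering schedule is fixed up front; the floor of 20 surviving cases keeps
the vote pool clinically meaningful for small case-bases.

The two reference measures rank the full case-base with no case selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

from .case_model import Case, CaseBase
from .cdt import ClinicalDecisionTree, attributes_through_level, level_weights
from .distance import (
    OrdinalDistanceMatrix,
    WeightVector,
    gwhsm_dissimilarity,
    heom_distance,
    matrices_for_schema,
    weighted_dissimilarity,
)

__all__ = [
    "DEFAULT_MIN_CASES",
    "RankedCase",
    "RetrievalResult",
    "MeasureSpec",
    "h_whsm_retrieve",
    "knn",
    "retrieve",
]

#: Survivor-count floor below which progressive case selection is disabled.
DEFAULT_MIN_CASES = 20


@dataclass(frozen=True)
class RankedCase:
    case_id: str
    dissimilarity: float
    rank: int  # 1-based


@dataclass(frozen=True)
class RetrievalResult:
    """Ranked retrieval output with the per-level survivor trace for audit."""

    candidate: str
    measure: str
    ranked: tuple[RankedCase, ...]
    level_trace: tuple[tuple[int, tuple[str, ...]], ...] = ()

    @property
    def dissimilarities(self) -> dict[str, float]:
        return {r.case_id: r.dissimilarity for r in self.ranked}

    def similarities(self) -> dict[str, float]:
        """Hierarchical/complement similarity ``1 - diss`` per ranked case."""
        return {r.case_id: 1.0 - r.dissimilarity for r in self.ranked}

    def to_dict(self) -> dict[str, Any]:
        return {
            "candidate": self.candidate,
            "measure": self.measure,
            "ranked": [
                {"case_id": r.case_id, "dissimilarity": r.dissimilarity, "rank": r.rank}
                for r in self.ranked
            ],
            "level_trace": [
                {"level": l, "surviving": list(ids), "size": len(ids)}
                for l, ids in self.level_trace
            ],
        }


@dataclass(frozen=True)
class MeasureSpec:
    """Which similarity measure to retrieve with.

    ``name`` is one of ``H_WHSM``, ``HEOM``, ``GWHSM``.  ``weights`` applies
    to GWHSM only (defaults to all-ones over the selected attributes);
    ``attrs`` restricts GWHSM to a subset of attributes (attribute
    selection), defaulting to the whole schema.
    """

    name: str
    weights: WeightVector | None = None
    attrs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in ("H_WHSM", "HEOM", "GWHSM"):
            raise ValueError(f"unknown measure {self.name!r}")


def _rank_sorted(diss: Mapping[str, float]) -> tuple[RankedCase, ...]:
    ordered = sorted(diss.items(), key=lambda kv: (kv[1], kv[0]))
    return tuple(
        RankedCase(case_id=cid, dissimilarity=d, rank=i + 1)
        for i, (cid, d) in enumerate(ordered)
    )


def h_whsm_retrieve(
    candidate: Case,
    cb: CaseBase,
    cdt: ClinicalDecisionTree,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
) -> RetrievalResult:
    """Hierarchical retrieval over the CDT with progressive case selection."""
    if cb.m < 1:
        raise ValueError("empty case-base")
    if any(c.id == candidate.id for c in cb.cases):
        raise ValueError(f"candidate {candidate.id!r} already in the case-base")
    schema = cb.schema_by_name
    cdt.validate_against(schema)
    matrices = matrices_for_schema(cb.schema, matrices)
    ranges = cb.ranges
    weights = level_weights(cdt)
    m = cb.m
    L = cdt.height

    survivors = [c.id for c in cb.cases]
    by_id = {c.id: c for c in cb.cases}
    trace: list[tuple[int, tuple[str, ...]]] = []
    diss: dict[str, float] = {}
    for l in range(1, L + 1):
        attrs = attributes_through_level(cdt, l)
        diss = {
            cid: weighted_dissimilarity(
                candidate, by_id[cid], attrs, weights, schema, matrices, ranges
            )
            for cid in survivors
        }
        if m / 2**l > min_cases and l != L:
            keep = math.ceil(len(survivors) / 2)
            ordered = sorted(diss.items(), key=lambda kv: (kv[1], kv[0]))
            survivors = [cid for cid, _ in ordered[:keep]]
        trace.append((l, tuple(survivors)))
    final = {cid: diss[cid] for cid in survivors}
    return RetrievalResult(
        candidate=candidate.id,
        measure="H_WHSM",
        ranked=_rank_sorted(final),
        level_trace=tuple(trace),
    )


def knn(
    result: RetrievalResult | Mapping[str, float],
    k: int,
) -> tuple[list[RankedCase], bool]:
    """Top-k cases by ascending dissimilarity (ties broken by case id).

    Returns ``(ranked, truncated)`` where ``truncated`` warns that fewer than
    ``k`` cases survived retrieval and the whole set was returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = result.ranked if isinstance(result, RetrievalResult) else _rank_sorted(result)
    if len(ranked) < k:
        return list(ranked), True
    return list(ranked[:k]), False


def retrieve(
    candidate: Case,
    cb: CaseBase,
    measure_spec: MeasureSpec | str,
    cdt: ClinicalDecisionTree | None = None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
) -> RetrievalResult:
    """Dispatch retrieval over the three measures.

    HEOM and GWHSM rank the full case-base (no case selection); the
    hierarchical measure delegates to :func:`h_whsm_retrieve` and needs a
    ``cdt``.
    """
    if isinstance(measure_spec, str):
        measure_spec = MeasureSpec(name=measure_spec)
    if measure_spec.name == "H_WHSM":
        if cdt is None:
            raise ValueError("H_WHSM retrieval needs a clinical decision tree")
        return h_whsm_retrieve(candidate, cb, cdt, matrices, min_cases)

    schema = cb.schema_by_name
    ranges = cb.ranges
    if measure_spec.name == "HEOM":
        diss = {c.id: heom_distance(candidate, c, schema, ranges) for c in cb.cases}
    else:  # GWHSM
        attrs = measure_spec.attrs or tuple(schema)
        w = measure_spec.weights or WeightVector.uniform(attrs)
        diss = {
            c.id: gwhsm_dissimilarity(candidate, c, w, schema, attrs, ranges)
            for c in cb.cases
        }
    ranked = _rank_sorted(diss)
    return RetrievalResult(
        candidate=candidate.id,
        measure=measure_spec.name,
        ranked=ranked,
        level_trace=((1, tuple(c.id for c in cb.cases)),),
    )
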