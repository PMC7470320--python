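"""Evaluation harness: leave-one-out and train/test cross validation.

Two criteria are computed per candidate case:

* retrieve-based — the candidate counts as correctly classified when its
  confirmed solution appears at least once among the k retrieved cases;
* reuse-based — correct when the weighted vote's suggested solution equals
  the confirmed solution.

Aggregates include the retrieve-hit rate, the reuse-correct rate, TPR/FPR at
k = 1 and one-vs-rest sensitivity/specificity per solution label.  The
multiclass TPR is the micro-averaged 1-NN accuracy (fraction of candidates
whose nearest neighbour carries the confirmed solution); the FPR is the
macro-average of the one-vs-rest false-positive rates over the labels present
in the test set.  Labels with no negative (or positive) test cases report
their specificity (or sensitivity) as absent rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

from .case_model import Case, CaseBase, remove_case
from .cdt import ClinicalDecisionTree
from .distance import OrdinalDistanceMatrix
from .retrieve import DEFAULT_MIN_CASES, MeasureSpec, knn, retrieve
from .reuse import suggest

__all__ = [
    "PerCase",
    "EvaluationReport",
    "retrieve_hit",
    "per_solution_metrics",
    "loocv",
    "holdout",
]


@dataclass(frozen=True)
class PerCase:
    """Outcome of one candidate evaluation."""

    candidate: str
    retrieved: tuple[str, ...]
    retrieved_solutions: tuple[str, ...]
    predicted_1nn: str | None
    suggested: str | None
    confirmed: str | None
    retrieve_hit: bool
    reuse_hit: bool


@dataclass(frozen=True)
class EvaluationReport:
    design: str  # "loocv" | "holdout"
    measure: str
    decision: str
    k: int
    per_case: tuple[PerCase, ...]
    aggregates: Mapping[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "design": self.design,
            "measure": self.measure,
            "decision": self.decision,
            "k": self.k,
            "aggregates": dict(self.aggregates),
        }


def retrieve_hit(retrieved_solutions: Sequence[str], confirmed: str | None) -> bool:
    """Retrieve-based criterion: confirmed solution among the k retrieved."""
    if not retrieved_solutions:
        raise ValueError("needs at least one retrieved case")
    return confirmed is not None and confirmed in retrieved_solutions


def per_solution_metrics(
    per_case: Sequence[PerCase], labels: Sequence[str] | None = None
) -> dict[str, dict[str, float | None]]:
    """One-vs-rest sensitivity/specificity of the 1-NN prediction per label.

    ``sensitivity(s)`` = fraction of confirmed-s cases predicted s;
    ``specificity(s)`` = fraction of confirmed-not-s cases predicted not-s.
    A label with no positives (or no negatives) in the test set reports that
    metric as None (absent).
    """
    entries = [pc for pc in per_case if pc.confirmed is not None]
    if labels is None:
        labels = sorted({pc.confirmed for pc in entries})
    table: dict[str, dict[str, float | None]] = {}
    for s in labels:
        tp = sum(1 for pc in entries if pc.confirmed == s and pc.predicted_1nn == s)
        fn = sum(1 for pc in entries if pc.confirmed == s and pc.predicted_1nn != s)
        fp = sum(1 for pc in entries if pc.confirmed != s and pc.predicted_1nn == s)
        tn = sum(1 for pc in entries if pc.confirmed != s and pc.predicted_1nn != s)
        table[s] = {
            "sensitivity": tp / (tp + fn) if tp + fn > 0 else None,
            "specificity": tn / (tn + fp) if tn + fp > 0 else None,
        }
    return table


def _evaluate_candidate(
    candidate: Case,
    train: CaseBase,
    measure_spec: MeasureSpec | str,
    decision: str,
    k: int,
    cdt: ClinicalDecisionTree | None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None,
    min_cases: int,
) -> PerCase:
    result = retrieve(candidate, train, measure_spec, cdt, matrices, min_cases)
    topk, _ = knn(result, k)
    solutions = train.solutions(decision)
    retrieved_sols = tuple(solutions.get(r.case_id) for r in topk)
    confirmed = candidate.solution.get(decision)
    top1, _ = knn(result, 1)
    predicted = solutions.get(top1[0].case_id) if top1 else None
    try:
        suggestion = suggest(topk, solutions, k=len(topk), decision=decision)
        suggested = suggestion.suggested
    except ValueError:
        suggested = None
    return PerCase(
        candidate=candidate.id,
        retrieved=tuple(r.case_id for r in topk),
        retrieved_solutions=tuple(s for s in retrieved_sols if s is not None),
        predicted_1nn=predicted,
        suggested=suggested,
        confirmed=confirmed,
        retrieve_hit=confirmed is not None and confirmed in retrieved_sols,
        reuse_hit=confirmed is not None and suggested == confirmed,
    )


def _aggregate(per_case: Sequence[PerCase]) -> dict[str, Any]:
    scored = [pc for pc in per_case if pc.confirmed is not None]
    n = len(scored)
    if n == 0:
        raise ValueError("no candidate carries a confirmed solution")
    tpr = sum(pc.predicted_1nn == pc.confirmed for pc in scored) / n
    table = per_solution_metrics(scored)
    fprs = [
        1.0 - m["specificity"] for m in table.values() if m["specificity"] is not None
    ]
    return {
        "n": n,
        "retrieve_hit_rate": sum(pc.retrieve_hit for pc in scored) / n,
        "reuse_correct_rate": sum(pc.reuse_hit for pc in scored) / n,
        "tpr": tpr,
        "fpr": sum(fprs) / len(fprs) if fprs else None,
        "per_solution": table,
    }


def loocv(
    cb: CaseBase,
    measure_spec: MeasureSpec | str,
    decision: str,
    k: int = 1,
    cdt: ClinicalDecisionTree | None = None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
) -> EvaluationReport:
    """Leave-one-out cross validation: each case retrieved against the rest."""
    if cb.m < 2:
        raise ValueError("leave-one-out needs at least two cases")
    if k >= cb.m:
        raise ValueError(f"k = {k} must be smaller than the case-base size {cb.m}")
    per_case = []
    for case in cb.cases:
        train = remove_case(cb, case.id)
        per_case.append(
            _evaluate_candidate(case, train, measure_spec, decision, k, cdt, matrices, min_cases)
        )
    name = measure_spec if isinstance(measure_spec, str) else measure_spec.name
    return EvaluationReport(
        design="loocv",
        measure=name,
        decision=decision,
        k=k,
        per_case=tuple(per_case),
        aggregates=_aggregate(per_case),
    )


def holdout(
    train: CaseBase,
    test: CaseBase,
    measure_spec: MeasureSpec | str,
    decision: str,
    k: int = 1,
    cdt: ClinicalDecisionTree | None = None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
) -> EvaluationReport:
    """Train/test cross validation: every test case against the full training set."""
    if [a.name for a in train.schema] != [a.name for a in test.schema]:
        raise ValueError("train and test case-bases must share the same schema")
    if k > train.m:
        raise ValueError(f"k = {k} exceeds the training case-base size {train.m}")
    per_case = [
        _evaluate_candidate(case, train, measure_spec, decision, k, cdt, matrices, min_cases)
        for case in test.cases
    ]
    name = measure_spec if isinstance(measure_spec, str) else measure_spec.name
    return EvaluationReport(
        design="holdout",
        measure=name,
        decision=decision,
        k=k,
        per_case=tuple(per_case),
        aggregates=_aggregate(per_case),
    )
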