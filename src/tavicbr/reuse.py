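"""Reuse step: suggest one solution from the retrieved cases by weighted vote.

Each retrieved case votes for its own solution with weight
``(k + 1 - rank) / diss``: nearer cases (small dissimilarity) and
better-ranked cases count more.  Vote scores are normalised to percentages
and reported as per-solution confidence; the suggested solution is the
argmax.  A dissimilarity of exactly zero (an exact duplicate) is clamped to
a tiny epsilon so the duplicate dominates the vote with a finite score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

from .retrieve import RankedCase

__all__ = ["DISS_EPS", "Suggestion", "vote_scores", "suggest"]

#: Lower clamp for dissimilarities in the vote weight (exact duplicates).
DISS_EPS = 1e-9


@dataclass(frozen=True)
class Suggestion:
    """Vote outcome for one decision: scores, winner and confidence (%) table."""

    decision: str
    votes: Mapping[str, float]
    suggested: str
    confidence: Mapping[str, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "decision": self.decision,
            "suggested": self.suggested,
            "confidence": dict(self.confidence),
        }


def vote_scores(
    retrieved: Sequence[RankedCase],
    solutions: Mapping[str, str],
    k: int | None = None,
    eps: float = DISS_EPS,
) -> dict[str, float]:
    """Distance- and rank-weighted vote score per solution label.

    ``score(s) = sum over retrieved cases with solution s of
    (k + 1 - rank) / max(diss, eps)``.
    """
    if not retrieved:
        raise ValueError("empty retrieved list")
    if k is None:
        k = len(retrieved)
    scores: dict[str, float] = {}
    for r in retrieved:
        label = solutions.get(r.case_id)
        if label is None:
            continue
        weight = (k + 1 - r.rank) / max(r.dissimilarity, eps)
        scores[label] = scores.get(label, 0.0) + weight
    if not scores:
        raise ValueError("no retrieved case carries a solution for this decision")
    return scores


def suggest(
    retrieved: Sequence[RankedCase],
    solutions: Mapping[str, str],
    k: int | None = None,
    decision: str = "",
    eps: float = DISS_EPS,
) -> Suggestion:
    """Suggested solution with per-label confidence percentages (sum 100)."""
    scores = vote_scores(retrieved, solutions, k, eps)
    total = sum(scores.values())
    # argmax with lexicographic tie-break for determinism
    winner = min(scores, key=lambda s: (-scores[s], s))
    confidence = {s: 100.0 * v / total for s, v in scores.items()}
    return Suggestion(decision=decision, votes=scores, suggested=winner, confidence=confidence)
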