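"""Genetic-algorithm attribute-weight learning for the GWHSM measure.

Each chromosome is a floating-point weight vector over the problem
attributes.  Fitness is the leave-one-out precision of 1-NN retrieval under
GWHSM with those weights: every case in turn is removed, its single most
similar remaining case retrieved, and the fraction of cases whose retrieved
neighbour carries the same confirmed solution is the fitness.  Evolution
uses roulette-wheel parent selection, whole-arithmetic crossover, per-gene
Gaussian mutation clipped to the weight bounds, and elitism (the top
fraction carried forward unchanged), so best-of-generation fitness never
decreases.

Fitness evaluation is vectorised: per-attribute pairwise distance matrices
and missing-value masks over the case-base are precomputed once, after which
each chromosome's leave-one-out pass is a handful of array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .case_model import MISSING, QUANTITATIVE, CaseBase
from .distance import OrdinalDistanceMatrix, WeightVector, matrices_for_schema

__all__ = ["GAConfig", "PairwiseGwhsm", "loo_precision_fitness", "learn_weights"]


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters.

    Defaults follow the configuration reported to give the best weight
    determination: crossover rate 0.75, mutation rate 0.20, 300 generations,
    roulette-wheel selection, 30% elitism.  Population size and the mutation
    scale are engine choices (50 chromosomes; Gaussian sigma 0.1 on unit
    weight bounds).
    """

    population_size: int = 50
    crossover_rate: float = 0.75
    mutation_rate: float = 0.20
    generations: int = 300
    elitism_fraction: float = 0.30
    seed: int = 0
    weight_bounds: tuple[float, float] = (0.0, 1.0)
    mutation_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0,1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 < self.elitism_fraction < 1.0:
            raise ValueError("elitism_fraction must lie in (0,1)")
        lo, hi = self.weight_bounds
        if lo < 0 or hi <= lo:
            raise ValueError("weight bounds must satisfy 0 <= low < high")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


class PairwiseGwhsm:
    """Precomputed per-attribute pairwise distances for fast GWHSM fitness.

    ``dist[a, i, j]`` is the GWHSM per-attribute distance between cases i and
    j for attribute a; ``valid[a, i, j]`` is False where the attribute is
    missing in either case (such attributes are discarded from the weighted
    mean).
    """

    def __init__(
        self,
        cb: CaseBase,
        attrs: Sequence[str] | None = None,
        matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    ) -> None:
        schema = cb.schema_by_name
        self.attrs = list(attrs) if attrs is not None else [a.name for a in cb.schema]
        self.case_ids = [c.id for c in cb.cases]
        ranges = cb.ranges
        if matrices is None:
            matrices = matrices_for_schema(cb.schema)
        m = cb.m
        A = len(self.attrs)
        dist = np.zeros((A, m, m))
        valid = np.ones((A, m, m), dtype=bool)
        for ai, name in enumerate(self.attrs):
            a = schema[name]
            vals = [c.attributes.get(name, MISSING) for c in cb.cases]
            miss = np.array([v is MISSING for v in vals])
            if a.kind == QUANTITATIVE:
                x = np.array([0.0 if v is MISSING else float(v) for v in vals])
                lo, hi = a.range if a.range is not None else ranges[name]
                span = hi - lo
                if span <= 0:
                    d = (x[:, None] != x[None, :]).astype(float)
                else:
                    d = np.minimum(np.abs(x[:, None] - x[None, :]) / span, 1.0)
            else:
                codes = np.array([-1 if v is MISSING else hash(v) for v in vals])
                d = (codes[:, None] != codes[None, :]).astype(float)
            dist[ai] = d
            valid[ai] = ~(miss[:, None] | miss[None, :])
        self.dist = dist * valid
        self.valid = valid.astype(float)

    def dissimilarity_matrix(self, w: np.ndarray) -> np.ndarray:
        """Pairwise GWHSM dissimilarities under weights ``w`` (len = n attrs).

        Pairs with no informative attribute get +inf (never a neighbour).
        """
        num = np.tensordot(w, self.dist, axes=1)
        den = np.tensordot(w, self.valid, axes=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            diss = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        return diss

    def loo_precision(self, w: np.ndarray, labels: Sequence[str | None]) -> float:
        """LOO 1-NN precision: fraction of cases whose nearest other case
        (ties to the earlier case in case-base order) shares their label."""
        diss = self.dissimilarity_matrix(w)
        np.fill_diagonal(diss, np.inf)
        nn = np.argmin(diss, axis=1)
        lab = np.asarray(labels, dtype=object)
        known = np.array([l is not None for l in labels])
        if not known.any():
            raise ValueError("no case carries a solution for this decision")
        hits = (lab[nn] == lab) & known & np.array([labels[j] is not None for j in nn])
        return float(hits.sum() / known.sum())


def loo_precision_fitness(
    w: WeightVector | Mapping[str, float],
    cb: CaseBase,
    decision: str,
    attrs: Sequence[str] | None = None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    precomputed: PairwiseGwhsm | None = None,
) -> float:
    """Leave-one-out 1-NN precision of GWHSM under the given weights."""
    if cb.m < 2:
        raise ValueError("leave-one-out needs at least two cases")
    pre = precomputed or PairwiseGwhsm(cb, attrs, matrices)
    weights = w.weights if isinstance(w, WeightVector) else dict(w)
    vec = np.array([float(weights.get(a, 0.0)) for a in pre.attrs])
    if vec.sum() <= 0:
        raise ValueError("degenerate weights: all zero over the selected attributes")
    sols = cb.solutions(decision)
    labels = [sols[cid] for cid in pre.case_ids]
    return pre.loo_precision(vec, labels)


def learn_weights(
    cb: CaseBase,
    decision: str,
    cfg: GAConfig | None = None,
    attrs: Sequence[str] | None = None,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
) -> tuple[WeightVector, list[float]]:
    """Evolve GWHSM attribute weights; returns (best weights, best-fitness history).

    Fully reproducible from ``cfg.seed``; the per-generation best fitness is
    non-decreasing thanks to elitism.
    """
    cfg = cfg or GAConfig()
    pre = PairwiseGwhsm(cb, attrs, matrices)
    sols = cb.solutions(decision)
    labels = [sols[cid] for cid in pre.case_ids]
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.weight_bounds
    P, A = cfg.population_size, len(pre.attrs)
    pop = rng.uniform(lo, hi, size=(P, A))
    n_elite = max(1, math.floor(P * cfg.elitism_fraction))

    def evaluate(pop: np.ndarray) -> np.ndarray:
        out = np.empty(len(pop))
        for i, chrom in enumerate(pop):
            out[i] = 0.0 if chrom.sum() <= 0 else pre.loo_precision(chrom, labels)
        return out

    history: list[float] = []
    best_chrom: np.ndarray | None = None
    best_fit = -1.0
    for gen in range(cfg.generations):
        fit = evaluate(pop)
        order = np.argsort(-fit, kind="stable")
        if fit[order[0]] > best_fit:
            best_fit = float(fit[order[0]])
            best_chrom = pop[order[0]].copy()
        history.append(best_fit)
        if gen == cfg.generations - 1:
            break
        elites = pop[order[:n_elite]].copy()
        # roulette-wheel parent selection (uniform fallback on all-zero fitness)
        total = fit.sum()
        probs = np.full(P, 1.0 / P) if total <= 0 else fit / total
        n_children = P - n_elite
        children = np.empty((n_children, A))
        i = 0
        while i < n_children:
            pa, pb = rng.choice(P, size=2, p=probs)
            c1, c2 = pop[pa].copy(), pop[pb].copy()
            if rng.random() < cfg.crossover_rate:
                alpha = rng.random()
                c1, c2 = alpha * c1 + (1 - alpha) * c2, alpha * c2 + (1 - alpha) * c1
            for child in (c1, c2):
                mask = rng.random(A) < cfg.mutation_rate
                child[mask] += rng.normal(0.0, cfg.mutation_sigma, size=mask.sum())
                np.clip(child, lo, hi, out=child)
                if i < n_children:
                    children[i] = child
                    i += 1
        pop = np.vstack([elites, children])
    assert best_chrom is not None
    return WeightVector(dict(zip(pre.attrs, best_chrom.tolist()))), history
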