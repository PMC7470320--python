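"""Label-preserving data augmentation and fully synthetic case-base generation.

Augmentation emulates how a clinical case-base is doubled for evaluation:
every problem attribute of a real case is perturbed — quantitative values by
up to ±10% (uniform), clipped to a clinically coherent interval; measurement
attributes tied to the solution resampled inside the solution-consistent
(device-IFU-style) window; ordinal grades moved at most one step; binary
flags kept — while the solution and result fields are copied unchanged, so
the per-solution distribution of the doubled case-base is exactly preserved.

The synthetic generator emulates the structure of the clinical case-base
(mixed attribute types, a trans-femoral access share above 80%) without any
real patient data.  In ``separable`` mode every attribute is drawn from a
narrow label-specific band (quantitative: the middle fifth of the label's
slice of the schema range; ordinal/binary: a fixed label-determined value),
so a nearest neighbour under any of the supported measures recovers the
label — the harness's smoke-test regime.  In ``noisy`` mode only the listed
informative attributes carry signal (wider bands) and the rest are uniform
noise, the regime used to probe weight learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .case_model import (
    BINARY,
    BINARY_VALUES,
    MISSING,
    ORDINAL,
    QUANTITATIVE,
    AttributeSchema,
    Case,
    CaseBase,
    SchemaError,
)
from . import defaults

__all__ = [
    "AugmentationSpec",
    "augment_case",
    "augment_case_base",
    "GeneratorProfile",
    "default_profile",
    "planted_profile",
    "generate_synthetic_case_base",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Parameters of the case-doubling augmentation.

    ``solution_consistent_ranges`` maps solution label -> attribute ->
    (lo, hi): attributes listed there are resampled uniformly inside the
    window of the case's label for ``decision`` instead of being jittered.
    """

    quantitative_jitter: float = 0.10
    ordinal_shift_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # -1, 0, +1
    decision: str = "prosthesis"
    solution_consistent_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantitative_jitter <= 0.5:
            raise ValueError("quantitative_jitter must lie in (0, 0.5]")
        if abs(sum(self.ordinal_shift_probs) - 1.0) > 1e-9:
            raise ValueError("ordinal shift probabilities must sum to 1")

    @classmethod
    def with_default_ifu(cls, **kwargs) -> "AugmentationSpec":
        decision, ranges = defaults.default_ifu_ranges()
        return cls(decision=decision, solution_consistent_ranges=ranges, **kwargs)


def _tied_attrs(spec: AugmentationSpec) -> set[str]:
    return {a for attrs in spec.solution_consistent_ranges.values() for a in attrs}


def augment_case(
    case: Case,
    spec: AugmentationSpec,
    schema: Sequence[AttributeSchema] | Mapping[str, AttributeSchema],
    rng: np.random.Generator,
    new_id: str | None = None,
) -> Case:
    """One generated case: perturbed problem, identical solution and result."""
    attrs = list(schema.values()) if isinstance(schema, Mapping) else list(schema)
    tied = _tied_attrs(spec)
    label = case.solution.get(spec.decision)
    new_attrs = {}
    for a in attrs:
        v = case.attributes.get(a.name, MISSING)
        if v is MISSING:
            new_attrs[a.name] = MISSING
            continue
        if a.kind == QUANTITATIVE:
            if a.name in tied:
                if label is None or label not in spec.solution_consistent_ranges or a.name not in spec.solution_consistent_ranges[label]:
                    raise SchemaError(
                        f"attribute {a.name!r} is solution-tied but label {label!r} "
                        f"has no configured consistent range"
                    )
                lo, hi = spec.solution_consistent_ranges[label][a.name]
                new_attrs[a.name] = float(rng.uniform(lo, hi))
            else:
                v = float(v)
                jittered = v * (1.0 + rng.uniform(-spec.quantitative_jitter, spec.quantitative_jitter))
                if a.range is not None:
                    jittered = float(np.clip(jittered, *a.range))
                new_attrs[a.name] = jittered
        elif a.kind == ORDINAL:
            cats = a.categories  # type: ignore[assignment]
            i = cats.index(v)
            shift = int(rng.choice((-1, 0, 1), p=spec.ordinal_shift_probs))
            new_attrs[a.name] = cats[min(max(i + shift, 0), len(cats) - 1)]
        else:
            new_attrs[a.name] = v
    return Case(
        id=new_id or f"{case.id}-gen",
        attributes=new_attrs,
        solution=dict(case.solution),
        result=dict(case.result),
    )


def augment_case_base(cb: CaseBase, spec: AugmentationSpec) -> CaseBase:
    """Double the case-base: originals plus one generated case per original.

    Solutions are copied, so per-label counts are exactly doubled; the whole
    procedure is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    generated = [augment_case(c, spec, cb.schema, rng) for c in cb.cases]
    return CaseBase(
        schema=cb.schema,
        decisions=cb.decisions,
        cases=[*cb.cases, *generated],
        results=cb.results,
    )


# -- fully synthetic generation ------------------------------------------------


@dataclass(frozen=True)
class GeneratorProfile:
    """Recipe for a synthetic case-base.

    ``mixture`` gives per-decision solution label weights (must sum to 1).
    ``target_decision`` is the decision whose label drives the attribute
    distributions.  In ``separable`` mode every attribute is informative for
    the target decision; in ``noisy`` mode only ``informative`` attributes
    are, the rest being uniform noise over their schema range.
    ``band_fraction`` is the width of the label band as a fraction of the
    label's slice of the range (0.2 in separable mode leaves a 4x margin
    between neighbouring labels).
    """

    schema: tuple[AttributeSchema, ...]
    decisions: Mapping[str, Sequence[str]]
    mixture: Mapping[str, Mapping[str, float]]
    target_decision: str
    mode: str = "separable"
    informative: tuple[str, ...] = ()
    band_fraction: float = 0.2
    results: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("separable", "noisy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for decision, weights in self.mixture.items():
            labels = set(self.decisions[decision])
            if set(weights) - labels:
                raise ValueError(f"mixture labels unknown for decision {decision!r}")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {decision!r} must sum to 1")


def default_profile(mode: str = "separable") -> GeneratorProfile:
    """Default TAVI-like profile: full schema, trans-femoral mass > 80%."""
    schema, decisions, results = defaults.default_schema()
    mixture = {
        "vascular_access": {
            "right trans-femoral": 0.42,
            "left trans-femoral": 0.40,
            "left trans-subclavian": 0.08,
            "trans-aortic": 0.05,
            "trans-apical": 0.05,
        },
        "prosthesis": {
            "Edwards Sapien XT 23": 0.30,
            "Edwards Sapien XT 26": 0.30,
            "Medtronic CoreValve 26": 0.20,
            "Medtronic CoreValve 29": 0.20,
        },
    }
    informative = () if mode == "separable" else (
        "iliofemoral_min_diameter_right",
        "iliofemoral_min_diameter_left",
    )
    return GeneratorProfile(
        schema=tuple(schema),
        decisions=decisions,
        mixture=mixture,
        target_decision="vascular_access",
        mode=mode,
        informative=informative,
        results=tuple(results),
    )


def planted_profile(n_noise: int = 4, n_labels: int = 2) -> GeneratorProfile:
    """Minimal weight-learning testbed: one perfectly predictive quantitative
    attribute plus ``n_noise`` pure-noise attributes over a small label set."""
    labels = [chr(ord("A") + i) for i in range(n_labels)]
    schema = [AttributeSchema(name="signal", kind=QUANTITATIVE, range=(0.0, 1.0))]
    schema += [
        AttributeSchema(name=f"noise_{i}", kind=QUANTITATIVE, range=(0.0, 1.0))
        for i in range(n_noise)
    ]
    return GeneratorProfile(
        schema=tuple(schema),
        decisions={"outcome": labels},
        mixture={"outcome": {s: 1.0 / n_labels for s in labels}},
        target_decision="outcome",
        mode="noisy",
        informative=("signal",),
        # wide within-label bands: the signal stays perfectly predictive
        # (label bands remain disjoint) but only dominates nearest-neighbour
        # geometry when its weight does — the regime weight learning must solve
        band_fraction=0.9,
    )


def _label_counts(weights: Mapping[str, float], n: int, labels: Sequence[str]) -> dict[str, int]:
    """Largest-remainder allocation of n cases to labels (deterministic)."""
    raw = {s: weights.get(s, 0.0) * n for s in labels}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s in sorted(labels, key=lambda s: (-(raw[s] - counts[s]), s))[:short]:
        counts[s] += 1
    return counts


def generate_synthetic_case_base(
    n: int, profile: GeneratorProfile | None = None, seed: int = 0
) -> CaseBase:
    """Draw a fully synthetic case-base of ``n`` cases from ``profile``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    profile = profile or default_profile()
    rng = np.random.default_rng(seed)

    target = profile.target_decision
    target_labels = list(profile.decisions[target])
    counts = _label_counts(profile.mixture[target], n, target_labels)
    assignments = [s for s in target_labels for _ in range(counts[s])]

    other_decisions = [d for d in profile.decisions if d != target]
    J = len(target_labels)
    cases = []
    for idx, label in enumerate(assignments):
        j = target_labels.index(label)
        attributes = {}
        for a in profile.schema:
            informative = profile.mode == "separable" or a.name in profile.informative
            if a.kind == QUANTITATIVE:
                lo, hi = a.range if a.range is not None else (0.0, 1.0)
                if informative:
                    width = (hi - lo) / J
                    margin = (1.0 - profile.band_fraction) / 2.0
                    b_lo = lo + (j + margin) * width
                    b_hi = lo + (j + 1 - margin) * width
                    attributes[a.name] = float(rng.uniform(b_lo, b_hi))
                else:
                    attributes[a.name] = float(rng.uniform(lo, hi))
            elif a.kind == ORDINAL:
                cats = a.categories  # type: ignore[assignment]
                attributes[a.name] = (
                    cats[j % len(cats)] if informative else str(rng.choice(cats))
                )
            else:
                attributes[a.name] = (
                    BINARY_VALUES[j % 2] if informative else str(rng.choice(BINARY_VALUES))
                )
        solution = {target: label}
        for d in other_decisions:
            w = profile.mixture.get(d)
            labels_d = list(profile.decisions[d])
            p = [w.get(s, 0.0) for s in labels_d] if w else None
            solution[d] = str(rng.choice(labels_d, p=p))
        result = {name: "" for name in profile.results}
        cases.append(
            Case(id=f"syn{idx:04d}", attributes=attributes, solution=solution, result={})
        )
    return CaseBase(
        schema=list(profile.schema),
        decisions={d: list(v) for d, v in profile.decisions.items()},
        cases=cases,
        results=list(profile.results),
    )
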