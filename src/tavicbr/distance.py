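"""Per-attribute distances and composite heterogeneous (dis)similarity measures.

The per-attribute dispatch: quantitative values compare by range-normalised
absolute difference, binary values by exact match (0/1), ordinal values by an
expert-built distance matrix, and any comparison involving a missing value
returns the neutral distance 0.5.  Composite dissimilarity is a weighted mean
of per-attribute distances, so it stays in [0,1]; similarity is its
complement.

Two reference measures from the CBR literature are included for comparison:
HEOM (heterogeneous Euclidean-overlap metric: overlap for qualitative
attributes, normalised Euclidean for quantitative, distance 1 on missing, no
weighting or attribute selection, root-sum-of-squares aggregation) and GWHSM
(weighted mean with Hamming distance for all categorical attributes and with
missing attributes discarded from the comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .case_model import (
    BINARY,
    MISSING,
    ORDINAL,
    QUANTITATIVE,
    AttributeSchema,
    Case,
    SchemaError,
)

__all__ = [
    "MISSING_VALUE_DISTANCE",
    "OrdinalDistanceMatrix",
    "WeightVector",
    "calcification_matrix",
    "default_matrix_for",
    "load_matrices",
    "attr_distance",
    "weighted_dissimilarity",
    "similarity",
    "heom_distance",
    "gwhsm_dissimilarity",
]

#: Neutral distance returned whenever either compared value is missing.
MISSING_VALUE_DISTANCE = 0.5

# Expert distance matrix for five-grade calcification (No..Massive).  Grade
# gaps are deliberately non-linear: No~Mild and Heavy~Massive are near, while
# crossing the Moderate midpoint costs much more.
_CALCIFICATION_CATEGORIES = ("No", "Mild", "Moderate", "Heavy", "Massive")
_CALCIFICATION_ENTRIES = np.array(
    [
        [0.00, 0.15, 0.50, 0.90, 1.00],
        [0.15, 0.00, 0.20, 0.50, 0.70],
        [0.50, 0.20, 0.00, 0.20, 0.50],
        [0.90, 0.50, 0.20, 0.00, 0.15],
        [1.00, 0.70, 0.50, 0.15, 0.00],
    ]
)


@dataclass(frozen=True)
class OrdinalDistanceMatrix:
    """Square table of unit-interval distances between ordinal categories."""

    attribute: str
    categories: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        e = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", e)
        n = len(self.categories)
        if e.shape != (n, n):
            raise SchemaError(
                f"matrix for {self.attribute!r}: shape {e.shape} != ({n},{n})"
            )
        if not np.allclose(e, e.T):
            raise SchemaError(f"matrix for {self.attribute!r} is not symmetric")
        if not np.allclose(np.diag(e), 0.0):
            raise SchemaError(f"matrix for {self.attribute!r} has non-zero diagonal")
        if e.min() < 0 or e.max() > 1:
            raise SchemaError(f"matrix for {self.attribute!r} has entries outside [0,1]")

    def distance(self, v1: str, v2: str) -> float:
        i = self.categories.index(v1)
        j = self.categories.index(v2)
        return float(self.entries[i, j])


def calcification_matrix(attribute: str = "calcification") -> OrdinalDistanceMatrix:
    """The expert five-grade calcification distance matrix."""
    return OrdinalDistanceMatrix(
        attribute=attribute,
        categories=_CALCIFICATION_CATEGORIES,
        entries=_CALCIFICATION_ENTRIES.copy(),
    )


def default_matrix_for(attribute: str, categories: Sequence[str]) -> OrdinalDistanceMatrix:
    """Default ordinal matrix for an attribute with no expert matrix on file.

    The five-grade calcification profile is mapped onto the attribute's own
    category count by bilinear interpolation of the reference table, so the
    same non-linear grade geometry applies at any scale length; for five
    categories the reference table is reproduced exactly.  Intended as an
    overridable default — expert matrices in config take precedence.
    """
    n = len(categories)
    if n < 2:
        raise SchemaError(f"attribute {attribute!r}: ordinal needs >= 2 categories")
    ref = _CALCIFICATION_ENTRIES
    pos = np.linspace(0.0, ref.shape[0] - 1.0, n)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = _bilinear(ref, pos[i], pos[j])
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return OrdinalDistanceMatrix(attribute=attribute, categories=tuple(categories), entries=out)


def _bilinear(grid: np.ndarray, x: float, y: float) -> float:
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    x1 = min(x0 + 1, grid.shape[0] - 1)
    y1 = min(y0 + 1, grid.shape[1] - 1)
    fx, fy = x - x0, y - y0
    return float(
        grid[x0, y0] * (1 - fx) * (1 - fy)
        + grid[x1, y0] * fx * (1 - fy)
        + grid[x0, y1] * (1 - fx) * fy
        + grid[x1, y1] * fx * fy
    )


def load_matrices(path: str | Path) -> dict[str, OrdinalDistanceMatrix]:
    """Read ordinal matrices from YAML/JSON.

    The document is a list of ``{attribute, categories, matrix}`` entries
    (``matrix`` row-major); each is validated for symmetry, zero diagonal and
    unit-interval bounds on load.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["matrices"] if isinstance(doc, Mapping) else doc
    out = {}
    for spec in entries:
        m = OrdinalDistanceMatrix(
            attribute=spec["attribute"],
            categories=tuple(spec["categories"]),
            entries=np.asarray(spec["matrix"], dtype=float),
        )
        out[m.attribute] = m
    return out


def matrices_for_schema(
    schema: Iterable[AttributeSchema],
    overrides: Mapping[str, OrdinalDistanceMatrix] | None = None,
) -> dict[str, OrdinalDistanceMatrix]:
    """Complete matrix set for every ordinal attribute (defaults + overrides)."""
    overrides = dict(overrides or {})
    out = {}
    for a in schema:
        if a.kind != ORDINAL:
            continue
        if a.name in overrides:
            out[a.name] = overrides[a.name]
        else:
            out[a.name] = default_matrix_for(a.name, a.categories)  # type: ignore[arg-type]
    return out


@dataclass(frozen=True)
class WeightVector:
    """Non-negative attribute weights ``w_a``."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, attr: str) -> float:
        return self.weights.get(attr, 0.0)

    @classmethod
    def uniform(cls, attrs: Iterable[str], value: float = 1.0) -> "WeightVector":
        return cls({a: value for a in attrs})


# -- per-attribute distance -----------------------------------------------


def attr_distance(
    attr: AttributeSchema,
    v1,
    v2,
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Unit-interval distance between two values of one attribute.

    Missing values (either side) short-circuit to the neutral distance 0.5.
    Quantitative distance is ``|v1-v2| / range_a`` clipped to [0,1] where
    ``range_a`` comes from the schema bounds or the ``ranges`` mapping frozen
    from the initial case-base.
    """
    if v1 is MISSING or v2 is MISSING:
        return MISSING_VALUE_DISTANCE
    if attr.kind == QUANTITATIVE:
        lo, hi = _resolve_range(attr, ranges)
        span = hi - lo
        if span <= 0:
            return 0.0 if float(v1) == float(v2) else 1.0
        return min(abs(float(v1) - float(v2)) / span, 1.0)
    if attr.kind == BINARY:
        return 0.0 if v1 == v2 else 1.0
    # ordinal
    if matrices is None or attr.name not in matrices:
        raise SchemaError(f"no ordinal distance matrix registered for {attr.name!r}")
    return matrices[attr.name].distance(v1, v2)


def _resolve_range(
    attr: AttributeSchema, ranges: Mapping[str, tuple[float, float]] | None
) -> tuple[float, float]:
    if attr.range is not None:
        return attr.range
    if ranges is not None and attr.name in ranges:
        return ranges[attr.name]
    raise SchemaError(
        f"attribute {attr.name!r}: no range declared and no observed range supplied"
    )


# -- composite measures -----------------------------------------------------


def weighted_dissimilarity(
    c1: Case,
    c2: Case,
    attrs: Sequence[str],
    w: WeightVector,
    schema: Mapping[str, AttributeSchema],
    matrices: Mapping[str, OrdinalDistanceMatrix] | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Weighted mean of per-attribute distances over ``attrs`` (in [0,1])."""
    if not attrs:
        raise ValueError("attrs must be non-empty")
    num = 0.0
    den = 0.0
    for name in attrs:
        wa = w[name]
        num += wa * attr_distance(schema[name], c1.value(name), c2.value(name), matrices, ranges)
        den += wa
    if den <= 0:
        raise ValueError("all weights are zero over the selected attributes")
    return num / den


def similarity(c1: Case, c2: Case, measure: Callable[[Case, Case], float]) -> float:
    """Complement similarity ``1 - diss`` of a unit-interval dissimilarity."""
    d = measure(c1, c2)
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"dissimilarity {d} outside [0,1]")
    return 1.0 - d


def heom_distance(
    c1: Case,
    c2: Case,
    schema: Mapping[str, AttributeSchema] | Sequence[AttributeSchema],
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Heterogeneous Euclidean-overlap metric over *all* schema attributes.

    Qualitative attributes (binary and ordinal, treated nominally) use the
    overlap distance 0/1; quantitative attributes use the range-normalised
    difference; a missing value on either side contributes distance 1.
    Aggregation is the root of the sum of squares.  No selection, no weights.
    """
    attrs = list(schema.values()) if isinstance(schema, Mapping) else list(schema)
    total = 0.0
    for a in attrs:
        v1, v2 = c1.value(a.name), c2.value(a.name)
        if v1 is MISSING or v2 is MISSING:
            d = 1.0
        elif a.kind == QUANTITATIVE:
            lo, hi = _resolve_range(a, ranges)
            span = hi - lo
            d = (0.0 if float(v1) == float(v2) else 1.0) if span <= 0 else min(
                abs(float(v1) - float(v2)) / span, 1.0
            )
        else:
            d = 0.0 if v1 == v2 else 1.0
        total += d * d
    return math.sqrt(total)


def gwhsm_dissimilarity(
    c1: Case,
    c2: Case,
    w: WeightVector,
    schema: Mapping[str, AttributeSchema],
    attrs: Sequence[str],
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Generalised weighted heterogeneous dissimilarity.

    Weighted mean over ``attrs`` with the normalised Euclidean distance for
    quantitative attributes and the Hamming (exact-match) distance for all
    categorical ones; an attribute missing in either case is discarded from
    both numerator and denominator.
    """
    if not attrs:
        raise ValueError("attrs must be non-empty")
    num = 0.0
    den = 0.0
    for name in attrs:
        a = schema[name]
        v1, v2 = c1.value(name), c2.value(name)
        if v1 is MISSING or v2 is MISSING:
            continue
        wa = w[name]
        if a.kind == QUANTITATIVE:
            lo, hi = _resolve_range(a, ranges)
            span = hi - lo
            d = (0.0 if float(v1) == float(v2) else 1.0) if span <= 0 else min(
                abs(float(v1) - float(v2)) / span, 1.0
            )
        else:
            d = 0.0 if v1 == v2 else 1.0
        num += wa * d
        den += wa
    if den <= 0:
        raise ValueError(
            "no informative attribute: every selected attribute is missing "
            "in one of the cases (or all weights are zero)"
        )
    return num / den
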