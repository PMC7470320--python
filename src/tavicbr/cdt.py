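"""Clinical decision trees (CDTs): expert attribute hierarchies per decision.

A CDT orders the attributes relevant to one decision into levels: level 1
holds the attributes the heart team examines first (hard gates such as
ilio-femoral diameters for the access route, or annulus dimensions for
prosthesis sizing), deeper levels hold refinements and preferences.  The
hierarchical similarity measure uses the tree in two ways: the attribute set
grows cumulatively level by level, and each attribute's weight decays
linearly with its depth, ``w = (L - l_a + 1) / L``, so root attributes weigh
1 and the deepest weigh 1/L.

The tree is used only for attribute selection, weighting and progressive
case filtering; its if/then contraindication rules are not executed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .case_model import AttributeSchema, SchemaError
from .distance import WeightVector

__all__ = [
    "ClinicalDecisionTree",
    "load_cdt",
    "attributes_through_level",
    "level_weights",
]


@dataclass(frozen=True)
class ClinicalDecisionTree:
    """Ordered attribute levels for one clinical decision."""

    decision: str
    levels: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        levels = tuple(tuple(lv) for lv in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 1 or any(len(lv) == 0 for lv in levels):
            raise SchemaError("a CDT needs >= 1 non-empty level")
        seen: dict[str, int] = {}
        for l, lv in enumerate(levels, start=1):
            for name in lv:
                if name in seen:
                    raise SchemaError(
                        f"attribute {name!r} appears at levels {seen[name]} and {l}"
                    )
                seen[name] = l

    @property
    def height(self) -> int:
        """Number of levels L."""
        return len(self.levels)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for lv in self.levels for a in lv)

    def level_of(self, attr: str) -> int:
        for l, lv in enumerate(self.levels, start=1):
            if attr in lv:
                return l
        raise SchemaError(f"attribute {attr!r} not in CDT for {self.decision!r}")

    def validate_against(self, schema: Iterable[AttributeSchema] | Mapping[str, AttributeSchema]) -> None:
        names = set(schema) if isinstance(schema, Mapping) else {a.name for a in schema}
        unknown = [a for a in self.attributes if a not in names]
        if unknown:
            raise SchemaError(f"CDT for {self.decision!r} references unknown attributes {unknown}")


def load_cdt(
    path: str | Path,
    schema: Iterable[AttributeSchema] | Mapping[str, AttributeSchema] | None = None,
) -> ClinicalDecisionTree:
    """Read a CDT config (keys ``decision``, ``levels: [[attr, ...], ...]``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cdt = ClinicalDecisionTree(decision=doc["decision"], levels=tuple(tuple(lv) for lv in doc["levels"]))
    if schema is not None:
        cdt.validate_against(schema)
    return cdt


def attributes_through_level(cdt: ClinicalDecisionTree, l: int) -> list[str]:
    """Cumulative attribute set of levels 1..l, level-major declaration order."""
    if not 1 <= l <= cdt.height:
        raise ValueError(f"level {l} outside [1, {cdt.height}]")
    return [a for lv in cdt.levels[:l] for a in lv]


def level_weights(cdt: ClinicalDecisionTree) -> WeightVector:
    """Level-decay weights ``w_a = (L - l_a + 1) / L``, in (0, 1]."""
    L = cdt.height
    return WeightVector(
        {a: (L - l + 1) / L for l, lv in enumerate(cdt.levels, start=1) for a in lv}
    )
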