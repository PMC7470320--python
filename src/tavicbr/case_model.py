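"""Typed case, attribute-schema and case-base model with CSV/config I/O.

A case is one patient: a problem vector of mixed-type clinical attributes
(quantitative measurements, expert-graded ordinal scales, yes/no flags), one
solution label per clinical decision (e.g. vascular access route, prosthesis
type+size), and free-form result fields recording procedure outcome.

The case-base CSV dialect is: first column ``case_id``, then one column per
problem attribute, then ``solution.<decision>`` columns, then
``result.<name>`` columns.  An empty cell or ``NA`` marks a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "QUANTITATIVE",
    "ORDINAL",
    "BINARY",
    "SchemaError",
    "ValidationError",
    "AttributeSchema",
    "Case",
    "CaseBase",
    "load_schema_config",
    "load_case_base",
    "write_case_base",
    "retain_case",
    "remove_case",
    "attribute_observed_range",
]

#: Internal sentinel for a missing attribute value.
MISSING = None

QUANTITATIVE = "quantitative"
ORDINAL = "ordinal"
BINARY = "binary"
_KINDS = (QUANTITATIVE, ORDINAL, BINARY)

#: Tokens accepted as "missing" when reading CSV cells.
_MISSING_TOKENS = ("", "NA")

#: Controlled vocabulary for binary attributes.
BINARY_VALUES = ("yes", "no")


class SchemaError(ValueError):
    """A schema/config is malformed or inconsistent with the data layout."""


class ValidationError(ValueError):
    """A case value violates its attribute schema."""


@dataclass(frozen=True)
class AttributeSchema:
    """Declaration of one problem attribute.

    Parameters
    ----------
    name
        Attribute identifier (CSV column name).
    kind
        One of ``quantitative``, ``ordinal``, ``binary``.
    range
        ``(min, max)`` bounds for quantitative attributes; optional — when
        absent the observed range of the initial case-base supplies the
        normalisation constant of the per-attribute distance.
    categories
        Ordered labels for ordinal attributes (worst-to-best or
        best-to-worst; only adjacency matters to augmentation).
    missing_code
        Token written for a missing value on CSV output.
    """

    name: str
    kind: str
    range: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None
    missing_code: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == QUANTITATIVE and self.range is not None:
            lo, hi = self.range
            if not lo < hi:
                raise SchemaError(
                    f"attribute {self.name!r}: range min must be < max, got {self.range}"
                )
        if self.kind == ORDINAL:
            if not self.categories or len(set(self.categories)) < 2:
                raise SchemaError(
                    f"attribute {self.name!r}: ordinal needs >= 2 distinct categories"
                )
            object.__setattr__(self, "categories", tuple(self.categories))

    def parse(self, token: str, case_id: str = "?") -> Any:
        """Parse a CSV token into a typed value or ``MISSING``."""
        if token in _MISSING_TOKENS or token == self.missing_code:
            return MISSING
        return self.validate(token, case_id)

    def validate(self, value: Any, case_id: str = "?") -> Any:
        """Coerce and check one non-missing value; raise ``ValidationError``."""
        if value is MISSING:
            return MISSING
        if self.kind == QUANTITATIVE:
            try:
                return float(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"case {case_id!r}, attribute {self.name!r}: "
                    f"non-numeric value {value!r}"
                ) from None
        value = str(value)
        if self.kind == ORDINAL:
            if value not in self.categories:  # type: ignore[operator]
                raise ValidationError(
                    f"case {case_id!r}, attribute {self.name!r}: value {value!r} "
                    f"not in categories {list(self.categories)}"  # type: ignore[arg-type]
                )
            return value
        if value not in BINARY_VALUES:
            raise ValidationError(
                f"case {case_id!r}, attribute {self.name!r}: binary value must be "
                f"one of {list(BINARY_VALUES)}, got {value!r}"
            )
        return value

    def format(self, value: Any) -> str:
        if value is MISSING:
            return self.missing_code
        if self.kind == QUANTITATIVE:
            v = float(value)
            return repr(int(v)) if v == int(v) else repr(v)
        return str(value)


@dataclass(frozen=True)
class Case:
    """One patient: problem attributes, per-decision solution, outcome."""

    id: str
    attributes: Mapping[str, Any]
    solution: Mapping[str, str] = field(default_factory=dict)
    result: Mapping[str, str] = field(default_factory=dict)

    def value(self, attr: str) -> Any:
        return self.attributes.get(attr, MISSING)


@dataclass
class CaseBase:
    """Ordered, validated collection of cases under one schema.

    Quantitative normalisation ranges (``range_a``) are frozen at
    construction from the schema bounds when declared, else from the observed
    min/max of the initial cases, and are *not* recomputed after progressive
    case filtering — this keeps per-attribute distances comparable across
    retrieval levels.
    """

    schema: list[AttributeSchema]
    decisions: dict[str, list[str]]
    cases: list[Case]
    results: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cases) < 1:
            raise ValidationError("a case-base needs at least one case")
        ids = [c.id for c in self.cases]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate case ids: {dup}")
        self._schema_by_name = {a.name: a for a in self.schema}
        self._validate_cases(self.cases)
        self._frozen_ranges = self._compute_ranges()

    # -- construction helpers -------------------------------------------------

    def _validate_cases(self, cases: Iterable[Case]) -> None:
        for case in cases:
            for name in case.attributes:
                if name not in self._schema_by_name:
                    raise SchemaError(
                        f"case {case.id!r}: unknown attribute {name!r}"
                    )
            for name, a in self._schema_by_name.items():
                a.validate(case.attributes.get(name, MISSING), case.id)
            for decision, label in case.solution.items():
                if decision not in self.decisions:
                    raise SchemaError(f"case {case.id!r}: unknown decision {decision!r}")
                if label is not MISSING and label not in self.decisions[decision]:
                    raise ValidationError(
                        f"case {case.id!r}: solution {label!r} not allowed for "
                        f"decision {decision!r} ({self.decisions[decision]})"
                    )

    def _compute_ranges(self) -> dict[str, tuple[float, float]]:
        ranges: dict[str, tuple[float, float]] = {}
        for a in self.schema:
            if a.kind != QUANTITATIVE:
                continue
            if a.range is not None:
                ranges[a.name] = a.range
                continue
            vals = [
                float(c.attributes[a.name])
                for c in self.cases
                if c.attributes.get(a.name) is not MISSING
            ]
            if vals:
                ranges[a.name] = (min(vals), max(vals))
        return ranges

    # -- accessors ------------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of cases."""
        return len(self.cases)

    @property
    def schema_by_name(self) -> dict[str, AttributeSchema]:
        return dict(self._schema_by_name)

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        """Frozen ``range_a`` normalisation bounds per quantitative attribute."""
        return dict(self._frozen_ranges)

    def attribute(self, name: str) -> AttributeSchema:
        try:
            return self._schema_by_name[name]
        except KeyError:
            raise SchemaError(f"unknown attribute {name!r}") from None

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.id == case_id:
                return c
        raise KeyError(case_id)

    def solutions(self, decision: str) -> dict[str, str]:
        """Map case id -> solution label for one decision."""
        if decision not in self.decisions:
            raise SchemaError(f"unknown decision {decision!r}")
        return {c.id: c.solution.get(decision) for c in self.cases}

    def subset(self, case_ids: Iterable[str]) -> "CaseBase":
        """Case-base restricted to ``case_ids`` (original order, frozen ranges kept)."""
        keep = set(case_ids)
        sub = CaseBase.__new__(CaseBase)
        sub.schema = self.schema
        sub.decisions = self.decisions
        sub.results = self.results
        sub.cases = [c for c in self.cases if c.id in keep]
        sub._schema_by_name = self._schema_by_name
        sub._frozen_ranges = self._frozen_ranges
        return sub


# -- config / CSV I/O ---------------------------------------------------------


def load_schema_config(path: str | Path) -> tuple[list[AttributeSchema], dict[str, list[str]], list[str]]:
    """Read a YAML/JSON schema document.

    Expected keys: ``attributes: [{name, kind, range|categories}]``,
    ``decisions: {name: [labels]}``, ``results: [names]``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_schema_config(doc)


def parse_schema_config(doc: Mapping[str, Any]) -> tuple[list[AttributeSchema], dict[str, list[str]], list[str]]:
    if not isinstance(doc, Mapping) or "attributes" not in doc:
        raise SchemaError("schema config must contain an 'attributes' list")
    attrs = []
    for spec in doc["attributes"]:
        rng = spec.get("range")
        attrs.append(
            AttributeSchema(
                name=spec["name"],
                kind=spec["kind"],
                range=tuple(rng) if rng is not None else None,
                categories=tuple(spec["categories"]) if spec.get("categories") else None,
            )
        )
    decisions = {k: list(v) for k, v in (doc.get("decisions") or {}).items()}
    results = list(doc.get("results") or [])
    return attrs, decisions, results


def load_case_base(path: str | Path, schema_config: str | Path | Mapping[str, Any]) -> CaseBase:
    """Read a case-base CSV under a schema config, validating every cell.

    Missing cells (empty or ``NA``) are stored as the missing marker; row
    order is preserved.  Unknown columns raise :class:`SchemaError`; values
    outside declared categories raise :class:`ValidationError` naming the
    offending case and attribute.
    """
    if isinstance(schema_config, Mapping):
        schema, decisions, results = parse_schema_config(schema_config)
    else:
        schema, decisions, results = load_schema_config(schema_config)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return case_base_from_frame(frame, schema, decisions, results)


def case_base_from_frame(
    frame: pd.DataFrame,
    schema: list[AttributeSchema],
    decisions: dict[str, list[str]],
    results: list[str],
) -> CaseBase:
    by_name = {a.name: a for a in schema}
    if frame.columns[0] != "case_id":
        raise SchemaError("first CSV column must be 'case_id'")
    for col in frame.columns[1:]:
        if col.startswith("solution."):
            if col[len("solution."):] not in decisions:
                raise SchemaError(f"unknown decision column {col!r}")
        elif col.startswith("result."):
            if col[len("result."):] not in results:
                raise SchemaError(f"unknown result column {col!r}")
        elif col not in by_name:
            raise SchemaError(f"unknown attribute column {col!r}")
    cases = []
    for _, row in frame.iterrows():
        cid = str(row["case_id"])
        attributes = {
            name: by_name[name].parse(str(row[name]), cid)
            for name in by_name
            if name in frame.columns
        }
        solution = {}
        for decision in decisions:
            col = f"solution.{decision}"
            if col in frame.columns and str(row[col]) not in _MISSING_TOKENS:
                solution[decision] = str(row[col])
        result = {}
        for name in results:
            col = f"result.{name}"
            if col in frame.columns and str(row[col]) not in _MISSING_TOKENS:
                result[name] = str(row[col])
        cases.append(Case(id=cid, attributes=attributes, solution=solution, result=result))
    return CaseBase(schema=schema, decisions=decisions, cases=cases, results=results)


def write_case_base(cb: CaseBase, path: str | Path) -> None:
    """Write the case-base in the CSV dialect (missing written as empty)."""
    cols: dict[str, list[str]] = {"case_id": [c.id for c in cb.cases]}
    for a in cb.schema:
        cols[a.name] = [a.format(c.attributes.get(a.name, MISSING)) for c in cb.cases]
    for decision in cb.decisions:
        cols[f"solution.{decision}"] = [c.solution.get(decision, "") or "" for c in cb.cases]
    for name in cb.results:
        cols[f"result.{name}"] = [c.result.get(name, "") or "" for c in cb.cases]
    pd.DataFrame(cols).to_csv(path, index=False)


# -- mutations (retain/remove are the engine-side part of the retain step) ----


def retain_case(cb: CaseBase, case: Case) -> CaseBase:
    """Return a new case-base with ``case`` appended (original order kept)."""
    if any(c.id == case.id for c in cb.cases):
        raise ValidationError(f"duplicate case id {case.id!r}")
    new = CaseBase(
        schema=cb.schema,
        decisions=cb.decisions,
        cases=[*cb.cases, case],
        results=cb.results,
    )
    return new


def remove_case(cb: CaseBase, case_id: str) -> CaseBase:
    """Return a new case-base without ``case_id``."""
    if not any(c.id == case_id for c in cb.cases):
        raise KeyError(case_id)
    return CaseBase(
        schema=cb.schema,
        decisions=cb.decisions,
        cases=[c for c in cb.cases if c.id != case_id],
        results=cb.results,
    )


def attribute_observed_range(cb: CaseBase, attr: str) -> tuple[float, float]:
    """Observed (min, max) of a quantitative attribute over non-missing values.

    Frozen semantics: callers should take this from the *initial* full
    case-base; :class:`CaseBase` does so itself at construction.
    """
    a = cb.attribute(attr)
    if a.kind != QUANTITATIVE:
        raise SchemaError(f"attribute {attr!r} is not quantitative")
    vals = [
        float(c.attributes[attr])
        for c in cb.cases
        if c.attributes.get(attr) is not MISSING
    ]
    if not vals:
        raise ValidationError(f"attribute {attr!r}: all values missing")
    return (min(vals), max(vals))
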