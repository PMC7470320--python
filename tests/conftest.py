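"""Shared fixtures: a tiny hand-written case-base and random-case machinery."""

from __future__ import annotations

import numpy as np
import pytest

from tavicbr.case_model import (
    BINARY,
    BINARY_VALUES,
    MISSING,
    ORDINAL,
    QUANTITATIVE,
    AttributeSchema,
    Case,
    CaseBase,
)
from tavicbr.distance import calcification_matrix, default_matrix_for

CALC_CATS = ("No", "Mild", "Moderate", "Heavy", "Massive")


@pytest.fixture
def simple_schema():
    return [
        AttributeSchema(name="diameter", kind=QUANTITATIVE, range=(18.0, 28.0)),
        AttributeSchema(name="calcification", kind=ORDINAL, categories=CALC_CATS),
        AttributeSchema(name="prior_disease", kind=BINARY),
    ]


@pytest.fixture
def matrices():
    return {"calcification": calcification_matrix()}


def make_case(cid, diameter=23.0, calcification="Mild", prior="no", access=None):
    sol = {"access": access} if access else {}
    return Case(
        id=cid,
        attributes={
            "diameter": diameter,
            "calcification": calcification,
            "prior_disease": prior,
        },
        solution=sol,
    )


@pytest.fixture
def toy_case_base(simple_schema):
    cases = [
        make_case("c1", 20.0, "No", "no", access="TF"),
        make_case("c2", 21.0, "Mild", "no", access="TF"),
        make_case("c3", 26.0, "Heavy", "yes", access="TA"),
        make_case("c4", 27.0, "Massive", "yes", access="TA"),
        make_case("c5", 23.0, "Moderate", "no", access="SC"),
    ]
    return CaseBase(
        schema=simple_schema,
        decisions={"access": ["TF", "SC", "TA"]},
        cases=cases,
    )


# -- random schema / case machinery for oracle tests ---------------------------


def random_schema(rng: np.random.Generator, max_attrs: int = 8):
    n = rng.integers(2, max_attrs + 1)
    attrs = []
    for i in range(n):
        kind = rng.choice([QUANTITATIVE, ORDINAL, BINARY])
        if kind == QUANTITATIVE:
            lo = float(rng.uniform(-10, 10))
            attrs.append(
                AttributeSchema(name=f"a{i}", kind=kind, range=(lo, lo + float(rng.uniform(0.5, 20))))
            )
        elif kind == ORDINAL:
            n_cat = int(rng.integers(2, 6))
            attrs.append(
                AttributeSchema(name=f"a{i}", kind=kind, categories=tuple(f"g{j}" for j in range(n_cat)))
            )
        else:
            attrs.append(AttributeSchema(name=f"a{i}", kind=kind))
    return attrs


def random_matrices(schema, rng: np.random.Generator):
    out = {}
    for a in schema:
        if a.kind != ORDINAL:
            continue
        n = len(a.categories)
        raw = rng.uniform(0, 1, size=(n, n))
        m = (raw + raw.T) / 2
        np.fill_diagonal(m, 0.0)
        from tavicbr.distance import OrdinalDistanceMatrix

        out[a.name] = OrdinalDistanceMatrix(attribute=a.name, categories=a.categories, entries=m)
    return out


def random_case(schema, rng: np.random.Generator, cid: str, missing_rate: float = 0.15, labels=None):
    attrs = {}
    for a in schema:
        if rng.random() < missing_rate:
            attrs[a.name] = MISSING
        elif a.kind == QUANTITATIVE:
            lo, hi = a.range
            span = hi - lo
            attrs[a.name] = float(rng.uniform(lo - 0.2 * span, hi + 0.2 * span))
        elif a.kind == ORDINAL:
            attrs[a.name] = str(rng.choice(a.categories))
        else:
            attrs[a.name] = str(rng.choice(BINARY_VALUES))
    sol = {"d": str(rng.choice(labels))} if labels else {}
    return Case(id=cid, attributes=attrs, solution=sol)
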