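"""Hierarchical retrieval against an independent brute-force transcription of
the level-by-level filtering algorithm, plus k-NN and dispatch contracts."""

import math

import numpy as np
import pytest

from tavicbr.case_model import CaseBase, Case
from tavicbr.cdt import ClinicalDecisionTree
from tavicbr.distance import WeightVector, attr_distance, weighted_dissimilarity
from tavicbr.retrieve import MeasureSpec, h_whsm_retrieve, knn, retrieve

from conftest import make_case, random_case, random_matrices, random_schema


def brute_force_hierarchical(candidate, cb, cdt, matrices, min_cases=20):
    """Literal transcription: explicit loops, full re-sort at every level."""
    L = cdt.height
    m = cb.m
    weights = {}
    for l, level in enumerate(cdt.levels, start=1):
        for a in level:
            weights[a] = (L - l + 1) / L
    schema = {a.name: a for a in cb.schema}
    ranges = cb.ranges
    survivors = [c for c in cb.cases]
    final = {}
    for l in range(1, L + 1):
        attrs = [a for level in cdt.levels[:l] for a in level]
        diss = {}
        for c in survivors:
            num, den = 0.0, 0.0
            for a in attrs:
                num += weights[a] * attr_distance(
                    schema[a], candidate.value(a), c.value(a), matrices, ranges
                )
                den += weights[a]
            diss[c.id] = num / den
        if m / 2**l > min_cases and l != L:
            order = sorted(survivors, key=lambda c: (diss[c.id], c.id))
            survivors = order[: math.ceil(len(survivors) / 2)]
            survivors = [c for c in cb.cases if c in survivors]  # stable order
        final = {c.id: diss[c.id] for c in survivors}
    ranked = sorted(final.items(), key=lambda kv: (kv[1], kv[0]))
    return [cid for cid, _ in ranked], final


def random_tree(schema, rng):
    names = [a.name for a in schema]
    rng.shuffle(names)
    L = int(rng.integers(1, min(3, len(names)) + 1))
    cuts = sorted(rng.choice(range(1, len(names)), size=L - 1, replace=False)) if L > 1 else []
    levels, start = [], 0
    for cut in [*cuts, len(names)]:
        levels.append(tuple(names[start:cut]))
        start = cut
    return ClinicalDecisionTree(decision="d", levels=tuple(levels))


def test_matches_brute_force_on_random_case_bases():
    """Oracle equivalence for case-bases up to 32 cases and trees up to L=3."""
    rng = np.random.default_rng(2024)
    for trial in range(40):
        schema = random_schema(rng, max_attrs=6)
        matrices = random_matrices(schema, rng)
        m = int(rng.integers(2, 33))
        cases = [random_case(schema, rng, f"c{i:02d}") for i in range(m)]
        cb = CaseBase(schema=schema, decisions={}, cases=cases)
        cdt = random_tree(schema, rng)
        candidate = random_case(schema, rng, "cand")
        min_cases = int(rng.choice([2, 5, 20]))
        result = h_whsm_retrieve(candidate, cb, cdt, matrices, min_cases=min_cases)
        want_order, want_diss = brute_force_hierarchical(candidate, cb, cdt, matrices, min_cases)
        assert [r.case_id for r in result.ranked] == want_order
        for r in result.ranked:
            assert r.dissimilarity == pytest.approx(want_diss[r.case_id], abs=1e-12)
        # survivor sets nest and halve (ceil) whenever the guard fires
        trace = result.level_trace
        for (l_prev, prev), (l_cur, cur) in zip(trace, trace[1:]):
            assert set(cur) <= set(prev)
            if cb.m / 2**l_cur > min_cases and l_cur != cdt.height:
                assert len(cur) == math.ceil(len(prev) / 2)
            else:
                assert len(cur) == len(prev)


def test_halving_schedule_for_138_cases(simple_schema, matrices):
    """m=138, L=3: 69 survive level 1, 35 level 2, final ranking over 35."""
    rng = np.random.default_rng(0)
    cases = [
        make_case(f"c{i:03d}", float(rng.uniform(18, 28)),
                  str(rng.choice(["No", "Mild", "Moderate", "Heavy", "Massive"])),
                  str(rng.choice(["yes", "no"])))
        for i in range(138)
    ]
    cb = CaseBase(schema=simple_schema, decisions={}, cases=cases)
    cdt = ClinicalDecisionTree(
        decision="d", levels=(("diameter",), ("calcification",), ("prior_disease",))
    )
    result = h_whsm_retrieve(make_case("cand", 22.0), cb, cdt, matrices)
    sizes = [len(ids) for _, ids in result.level_trace]
    assert sizes == [69, 35, 35]
    assert len(result.ranked) == 35


def test_small_case_base_never_filters(simple_schema, matrices):
    """m=16: 16/2 = 8 <= 20, so every level ranks all 16 cases."""
    cases = [make_case(f"c{i:02d}", 18.0 + i * 0.5) for i in range(16)]
    cb = CaseBase(schema=simple_schema, decisions={}, cases=cases)
    cdt = ClinicalDecisionTree(decision="d", levels=(("diameter",), ("calcification",)))
    result = h_whsm_retrieve(make_case("cand", 23.0), cb, cdt, matrices)
    assert all(len(ids) == 16 for _, ids in result.level_trace)
    assert len(result.ranked) == 16


def test_single_level_tree_equals_flat_weighted_dissimilarity(simple_schema, matrices):
    """A one-level tree covering all attributes gives unit weights, so the
    hierarchical ranking equals plain weighted-mean ranking."""
    rng = np.random.default_rng(5)
    cases = [
        make_case(f"c{i}", float(rng.uniform(18, 28)),
                  str(rng.choice(["No", "Mild", "Heavy"])), str(rng.choice(["yes", "no"])))
        for i in range(12)
    ]
    cb = CaseBase(schema=simple_schema, decisions={}, cases=cases)
    attrs = [a.name for a in simple_schema]
    cdt = ClinicalDecisionTree(decision="d", levels=(tuple(attrs),))
    candidate = make_case("cand", 21.0, "Mild", "no")
    result = h_whsm_retrieve(candidate, cb, cdt, matrices)
    schema = cb.schema_by_name
    w = WeightVector.uniform(attrs)
    for r in result.ranked:
        want = weighted_dissimilarity(candidate, cb.case(r.case_id), attrs, w, schema, matrices, cb.ranges)
        assert r.dissimilarity == pytest.approx(want, abs=1e-15)


def test_candidate_inside_case_base_rejected(toy_case_base, matrices):
    cdt = ClinicalDecisionTree(decision="d", levels=(("diameter",),))
    with pytest.raises(ValueError, match="already"):
        h_whsm_retrieve(toy_case_base.cases[0], toy_case_base, cdt, matrices)


def test_determinism_on_ties(simple_schema, matrices):
    cases = [make_case(f"c{i}", 20.0) for i in range(6)]  # all identical
    cb = CaseBase(schema=simple_schema, decisions={}, cases=cases)
    cdt = ClinicalDecisionTree(decision="d", levels=(("diameter",),))
    r1 = h_whsm_retrieve(make_case("cand", 20.0), cb, cdt, matrices)
    r2 = h_whsm_retrieve(make_case("cand", 20.0), cb, cdt, matrices)
    assert r1 == r2
    assert [r.case_id for r in r1.ranked] == sorted(c.id for c in cases)  # id tie-break


# -- knn ------------------------------------------------------------------------


def test_knn_basics():
    ranked, truncated = knn({"A": 0.1, "B": 0.2}, 1)
    assert [r.case_id for r in ranked] == ["A"] and not truncated
    ranked, truncated = knn({"A": 0.1, "B": 0.2}, 5)
    assert len(ranked) == 2 and truncated
    with pytest.raises(ValueError):
        knn({"A": 0.1}, 0)


def test_knn_tie_at_cut_keeps_lower_id():
    ranked, _ = knn({"B": 0.2, "A": 0.2, "C": 0.1}, 2)
    assert [r.case_id for r in ranked] == ["C", "A"]
    assert [r.rank for r in ranked] == [1, 2]


# -- dispatch -------------------------------------------------------------------


def test_heom_ranks_exact_duplicate_first(toy_case_base):
    dup = toy_case_base.cases[2]
    candidate = Case(id="cand", attributes=dict(dup.attributes))
    result = retrieve(candidate, toy_case_base, "HEOM")
    assert result.ranked[0].case_id == dup.id
    assert result.ranked[0].dissimilarity == 0.0
    assert len(result.ranked) == toy_case_base.m  # no case selection


def test_each_measure_returns_sorted_ranking(toy_case_base, matrices):
    cdt = ClinicalDecisionTree(decision="access", levels=(("diameter",), ("calcification",)))
    candidate = make_case("cand", 22.0, "Mild", "no")
    for spec in ("HEOM", "GWHSM", "H_WHSM"):
        result = retrieve(candidate, toy_case_base, spec, cdt=cdt, matrices=matrices)
        diss = [r.dissimilarity for r in result.ranked]
        assert diss == sorted(diss)
        assert [r.rank for r in result.ranked] == list(range(1, len(diss) + 1))


def test_unknown_measure_rejected(toy_case_base):
    with pytest.raises(ValueError, match="unknown measure"):
        retrieve(toy_case_base.cases[0], toy_case_base, "COSINE")


def test_gwhsm_weights_silence_a_noise_attribute(simple_schema, matrices):
    """Down-weighting a pure-noise attribute changes the ranking on a toy
    where the diameter alone carries the signal."""
    cases = [
        make_case("near", 21.0, "Massive", "no"),
        make_case("far", 27.0, "Mild", "no"),
    ]
    cb = CaseBase(schema=simple_schema, decisions={}, cases=cases)
    candidate = make_case("cand", 20.0, "Mild", "no")
    flat = retrieve(candidate, cb, MeasureSpec(name="GWHSM"))
    learned = retrieve(
        candidate, cb,
        MeasureSpec(name="GWHSM", weights=WeightVector({"diameter": 1.0, "calcification": 0.0, "prior_disease": 0.0})),
    )
    assert flat.ranked[0].case_id == "far"
    assert learned.ranked[0].case_id == "near"
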