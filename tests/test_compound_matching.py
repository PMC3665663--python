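"""Compound matching: features, name gate, contradictions, duplicates."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concord.compound_matching import (
    ALL_BUT_ONE,
    EXACT_STEREO,
    FINGERPRINT_STRUCT,
    CompoundMatchConfig,
    all_but_one_candidates,
    canonicalize_name,
    detect_duplicate_compounds,
    duplicate_compound_count,
    exact_stereo_feature,
    fingerprint_structure_feature,
    infer_compound_matches,
    tanimoto,
)
from concord.correspondence import CorrespondenceSet, Link
from concord.db_model import (
    CompoundRecord,
    PathwayDB,
    ReactionParticipant,
    ReactionRecord,
    Side,
)


@pytest.mark.parametrize(
    "left, right",
    [
        ("D-Glucose", "d glucose"),
        ("A.T.P.", "ATP"),
        ("alpha-KETO-glutarate", "alphaketoglutarate"),
    ],
)
def test_canonicalize_equates_punctuation_and_case(left, right):
    assert canonicalize_name(left) == canonicalize_name(right)


def test_canonicalize_examples():
    assert canonicalize_name("L-alanine!") == "lalanine"
    assert canonicalize_name("") == ""


def test_tanimoto_values():
    assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0
    assert tanimoto({1}, {2}) == 0.0
    assert tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5
    with pytest.raises(ValueError):
        tanimoto(set(), set())


@settings(max_examples=100, deadline=None)
@given(
    st.sets(st.integers(0, 63), max_size=20),
    st.sets(st.integers(0, 63), max_size=20),
)
def test_tanimoto_matches_brute_force(a, b):
    if not a and not b:
        return
    expected = len([x for x in a if x in b]) / len(set(list(a) + list(b)))
    assert tanimoto(a, b) == pytest.approx(expected)


def _cpd(cid, name, fp=None, pik=None, inchi=None, synonyms=()):
    return CompoundRecord(
        id=cid,
        common_name=name,
        synonyms=list(synonyms),
        fingerprint=frozenset(fp) if fp is not None else None,
        protonation_invariant_key=pik,
        inchi=inchi,
    )


def test_fingerprint_feature_thresholds():
    cfg = CompoundMatchConfig()
    a = _cpd("a", "x", fp=range(8), pik="k1")
    b_same = _cpd("b", "x", fp=range(8), pik="k1")
    assert fingerprint_structure_feature(a, b_same, cfg)
    a6 = _cpd("a", "x", fp=[0, 1, 2, 3, 4, 5], pik="k1")
    b6 = _cpd("b", "x", fp=[0, 1, 2, 3, 4, 6], pik="k1")  # 5/7 ~ 0.714
    assert not fingerprint_structure_feature(a6, b6, cfg)
    # tanimoto exactly at the threshold must NOT fire (strict >)
    exact = _cpd("a", "x", fp=[0, 1, 2], pik="k1")
    edge = _cpd("b", "x", fp=[0, 1, 2, 3], pik="k1")  # 3/4 = 0.75 exactly
    assert tanimoto(exact.fingerprint, edge.fingerprint) == 0.75
    assert not fingerprint_structure_feature(exact, edge, cfg)
    # protonation-invariant key gate
    b_key = _cpd("b", "x", fp=range(8), pik="k2")
    assert not fingerprint_structure_feature(a, b_key, cfg)
    # missing data is false, not an error
    assert not fingerprint_structure_feature(a, _cpd("b", "x"), cfg)


def test_exact_stereo_feature():
    a = _cpd("a", "x", inchi="InChI=1X/s1/h2/t3")
    assert exact_stereo_feature(a, _cpd("b", "x", inchi="InChI=1X/s1/h2/t3"))
    assert not exact_stereo_feature(a, _cpd("b", "x", inchi="InChI=1X/s1/h2/t4"))
    assert not exact_stereo_feature(a, _cpd("b", "x"))


def _db_with(compounds, reactions=()):
    db = PathwayDB()
    for c in compounds:
        db.compounds[c.id] = c
    for r in reactions:
        db.reactions[r.id] = r
    db.validate()
    return db


def _rxn(rid, lefts, rights):
    return ReactionRecord(
        rid,
        [ReactionParticipant(c, 1, Side.LEFT) for c in lefts]
        + [ReactionParticipant(c, 1, Side.RIGHT) for c in rights],
    )


def test_all_but_one_candidate_rules():
    db_a = _db_with(
        [_cpd(c, c) for c in ("A", "B", "C")],
        [_rxn("ra", ["A", "B"], ["C"])],
    )
    db_b = _db_with(
        [_cpd(c, c.lower()) for c in ("A2", "B2", "C2")],
        [_rxn("rb", ["A2", "B2"], ["C2"])],
    )
    links = {"A": "A2", "B": "B2"}
    rev = {v: k for k, v in links.items()}
    cands = all_but_one_candidates({("ra", "rb")}, links, rev, db_a, db_b)
    assert [(c.c_m, c.c_k) for c in cands] == [("C", "C2")]
    # two unmatched pairs -> no candidate
    cands = all_but_one_candidates(
        {("ra", "rb")}, {"A": "A2"}, {"A2": "A"}, db_a, db_b
    )
    assert cands == []
    # residual already linked elsewhere -> no candidate
    links2 = {"A": "A2", "B": "B2", "C": "X"}
    rev2 = {"A2": "A", "B2": "B", "X": "C"}
    assert (
        all_but_one_candidates({("ra", "rb")}, links2, rev2, db_a, db_b) == []
    )


def test_name_gate_blocks_structure_identity():
    a = _cpd("a1", "citrate", inchi="I1")
    b = _cpd("b1", "isocitrate", inchi="I1")
    matches, contras = infer_compound_matches(
        _db_with([a]), _db_with([b])
    )
    assert matches == [] and contras == []


def test_contradiction_drops_all_implicated_pairs():
    a = _cpd("a1", "malate", inchi="I1")
    b1 = _cpd("b1", "malate", inchi="I1")
    b2 = _cpd("b2", "Malate.", inchi="I1")
    matches, contras = infer_compound_matches(
        _db_with([a]), _db_with([b1, b2])
    )
    assert matches == []
    assert len(contras) == 1
    assert contras[0].compound_id == "a1"
    assert contras[0].partners == ("b1", "b2")


def test_curated_links_never_overridden():
    a = _cpd("a1", "fumarate", inchi="I1")
    b1 = _cpd("b1", "fumarate", inchi="I2")
    b2 = _cpd("b2", "fumarate", inchi="I1")
    existing = CorrespondenceSet([Link("compound", "a1", "b1", "curated")])
    matches, _ = infer_compound_matches(
        _db_with([a]), _db_with([b1, b2]), existing
    )
    assert [(m.a_id, m.b_id, m.source) for m in matches] == [
        ("a1", "b1", "curated")
    ]


def test_all_but_one_iterates_to_fixpoint():
    """Each inferred compound link completes the next reaction pair."""
    db_a = _db_with(
        [_cpd(c, c) for c in ("A", "B", "C", "D")],
        [_rxn("r1", ["A"], ["B"]), _rxn("r2", ["B"], ["C"]), _rxn("r3", ["C"], ["D"])],
    )
    db_b = _db_with(
        [_cpd(c + "x", c) for c in ("A", "B", "C", "D")],
        [
            _rxn("s1", ["Ax"], ["Bx"]),
            _rxn("s2", ["Bx"], ["Cx"]),
            _rxn("s3", ["Cx"], ["Dx"]),
        ],
    )
    existing = CorrespondenceSet(
        [Link("compound", "A", "Ax", "curated")]
        + [
            Link("reaction", r, s, "curated")
            for r, s in (("r1", "s1"), ("r2", "s2"), ("r3", "s3"))
        ]
    )
    matches, _ = infer_compound_matches(db_a, db_b, existing)
    inferred = {(m.a_id, m.b_id) for m in matches if m.source == "inferred"}
    assert inferred == {("B", "Bx"), ("C", "Cx"), ("D", "Dx")}
    assert all(
        m.features == {ALL_BUT_ONE}
        for m in matches
        if m.source == "inferred"
    )


def test_zero_noise_recovery_exact(zero_twin):
    db_a, db_b, truth = zero_twin
    matches, contras = infer_compound_matches(db_a, db_b)
    assert {(m.a_id, m.b_id) for m in matches} == truth.compound_pairs
    assert contras == []


def test_output_one_to_one_and_symmetric(default_twin):
    db_a, db_b, _ = default_twin
    matches, _ = infer_compound_matches(db_a, db_b)
    a_ids = [m.a_id for m in matches]
    b_ids = [m.b_id for m in matches]
    assert len(a_ids) == len(set(a_ids))
    assert len(b_ids) == len(set(b_ids))
    swapped, _ = infer_compound_matches(db_b, db_a)
    assert {(m.b_id, m.a_id) for m in swapped} == {
        (m.a_id, m.b_id) for m in matches
    }


def test_threshold_monotonicity_on_contradiction_free_fixture(zero_twin):
    db_a, db_b, _ = zero_twin
    strict, _ = infer_compound_matches(
        db_a, db_b, cfg=CompoundMatchConfig(tanimoto_threshold=0.9)
    )
    loose, _ = infer_compound_matches(
        db_a, db_b, cfg=CompoundMatchConfig(tanimoto_threshold=0.5)
    )
    assert {(m.a_id, m.b_id) for m in strict} <= {
        (m.a_id, m.b_id) for m in loose
    }


def test_duplicate_detection_by_structure_string():
    c1 = _cpd("c1", "x", inchi="I1")
    c2 = _cpd("c2", "y", inchi="I1")
    c3 = _cpd("c3", "z", inchi="I1")
    c4 = _cpd("c4", "w")  # no structure: never clusters
    c5 = _cpd("c5", "v", inchi="I2")
    db = _db_with([c1, c2, c3, c4, c5])
    assert detect_duplicate_compounds(db) == [["c1", "c2", "c3"]]
    assert duplicate_compound_count(db) == 2


def test_duplicate_injections_found(default_twin):
    db_a, _, truth = default_twin
    injected = {
        (kept, dup)
        for d, kept, dup in truth.injected_duplicates
        if d == "DB-A" and kept in db_a.compounds
    }
    clusters = detect_duplicate_compounds(db_a)
    clustered = {c for cl in clusters for c in cl}
    for kept, dup in injected:
        assert kept in clustered and dup in clustered
    assert duplicate_compound_count(db_a) == len(injected)
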