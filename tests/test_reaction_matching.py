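"""Reaction matching: stoichiometric embedding, cosine gate, EC fallback."""

import math

import pytest

from concord.correspondence import CorrespondenceSet, Link
from concord.db_model import (
    CompoundRecord,
    PathwayDB,
    ReactionParticipant,
    ReactionRecord,
    Side,
)
from concord.reaction_matching import (
    ReactionMatchConfig,
    activity_name_feature,
    build_stoich_matrix,
    cosine_similarity,
    detect_duplicate_reactions,
    duplicate_reaction_count,
    ec_feature,
    infer_reaction_matches,
    uniprot_feature,
)


def _cpd(cid):
    return CompoundRecord(id=cid, common_name=cid)


def _rxn(rid, lefts, rights, **kw):
    parts = [
        ReactionParticipant(c, k, Side.LEFT) for c, k in lefts
    ] + [ReactionParticipant(c, k, Side.RIGHT) for c, k in rights]
    return ReactionRecord(rid, parts, **kw)


def _db(compounds, reactions):
    db = PathwayDB()
    for c in compounds:
        db.compounds[c] = _cpd(c)
    for r in reactions:
        db.reactions[r.id] = r
    db.validate()
    return db


@pytest.fixture
def linked_pair_dbs():
    db_a = _db(
        ["A", "B", "C"],
        [_rxn("ra", [("A", 1), ("B", 1)], [("C", 1)], ec_numbers=["1.1.1.1"])],
    )
    db_b = _db(
        ["A2", "B2", "C2"],
        [_rxn("rb", [("A2", 1), ("B2", 1)], [("C2", 1)], ec_numbers=["1.1.1.1"])],
    )
    links = {"A": "A2", "B": "B2", "C": "C2"}
    return db_a, db_b, links


def test_linked_compounds_share_rows(linked_pair_dbs):
    db_a, db_b, links = linked_pair_dbs
    m = build_stoich_matrix(db_a, db_b, links)
    assert m.column("A", "ra") == m.column("B", "rb")


def test_no_links_means_disjoint_support(linked_pair_dbs):
    db_a, db_b, _ = linked_pair_dbs
    m = build_stoich_matrix(db_a, db_b, {})
    ca, cb = m.column("A", "ra"), m.column("B", "rb")
    assert set(ca) & set(cb) == set()


def test_coefficient_sign_convention():
    db = _db(["A", "B"], [_rxn("r", [("A", 2)], [("B", 1)])])
    m = build_stoich_matrix(db, PathwayDB(), {})
    col = m.column("A", "r")
    assert sorted(col.values()) == [-2, 1]


def test_unknown_compound_link_is_error(linked_pair_dbs):
    db_a, db_b, _ = linked_pair_dbs
    with pytest.raises(KeyError):
        build_stoich_matrix(db_a, db_b, {"ghost": "A2"})


def test_cosine_values():
    u = {0: -1, 1: -1, 2: 1}
    assert cosine_similarity(u, u) == pytest.approx(1.0)
    neg = {k: -v for k, v in u.items()}
    assert cosine_similarity(u, neg) == pytest.approx(-1.0)
    v = {0: -1, 2: 1}
    assert cosine_similarity(u, v) == pytest.approx(2 / math.sqrt(6))
    with pytest.raises(ValueError):
        cosine_similarity(u, {})


def test_annotation_features():
    ra = _rxn("ra", [("A", 1)], [("B", 1)],
              uniprot_accessions=["P00001"], ec_numbers=["1.1.1.1"],
              activity_names=["Alcohol dehydrogenase."])
    rb = _rxn("rb", [("C", 1)], [("D", 1)],
              uniprot_accessions=["P00001", "P99999"], ec_numbers=["1.1.1.2"],
              activity_names=["alcohol-dehydrogenase"])
    assert uniprot_feature(ra, rb)
    assert not ec_feature(ra, rb)
    assert activity_name_feature(ra, rb)
    # partial EC strings only match identical partial strings
    r1 = _rxn("r1", [("A", 1)], [("B", 1)], ec_numbers=["1.1.1.-"])
    r2 = _rxn("r2", [("A", 1)], [("B", 1)], ec_numbers=["1.1.1.1"])
    r3 = _rxn("r3", [("A", 1)], [("B", 1)], ec_numbers=["1.1.1.-"])
    assert not ec_feature(r1, r2)
    assert ec_feature(r1, r3)


def test_cosine_alone_insufficient(linked_pair_dbs):
    db_a, db_b, links = linked_pair_dbs
    db_a.reactions["ra"].ec_numbers = []
    db_b.reactions["rb"].ec_numbers = []
    matches, _ = infer_reaction_matches(db_a, db_b, links)
    assert matches == []


def test_feature_alone_insufficient_low_cosine():
    # A+B -> C vs A' -> D': cosine over the shared row only is 1/sqrt(6) < 0.6
    db_a = _db(["A", "B", "C"], [_rxn("ra", [("A", 1), ("B", 1)], [("C", 1)],
                                      uniprot_accessions=["P1"])])
    db_b = _db(["A2", "D2"], [_rxn("rb", [("A2", 1)], [("D2", 1)],
                                   uniprot_accessions=["P1"])])
    matches, _ = infer_reaction_matches(
        db_a, db_b, {"A": "A2"}, cfg=ReactionMatchConfig(ec_fallback=False)
    )
    assert matches == []


def test_ec_fallback_requires_one_to_one():
    mk = lambda rid, c1, c2, ec: _rxn(rid, [(c1, 1)], [(c2, 1)], ec_numbers=[ec])
    db_a = _db(["A", "B", "C", "D"],
               [mk("ra1", "A", "B", "9.9.9.9"), mk("ra2", "C", "D", "8.8.8.8")])
    db_b = _db(["W", "X", "Y", "Z"],
               [mk("rb1", "W", "X", "9.9.9.9"), mk("rb2", "Y", "Z", "9.9.9.9")])
    # no compound links: cosine support disjoint, main rule fires nothing;
    # EC 9.9.9.9 maps one A-reaction to TWO B-reactions -> ambiguous, no match
    matches, _ = infer_reaction_matches(db_a, db_b, {})
    assert matches == []
    # making the mapping unique enables the fallback
    db_b.reactions["rb2"].ec_numbers = ["7.7.7.7"]
    matches, _ = infer_reaction_matches(db_a, db_b, {})
    assert [(m.a_id, m.b_id, m.via_ec_fallback) for m in matches] == [
        ("ra1", "rb1", True)
    ]


def test_reversed_reaction_matches_via_absolute_cosine():
    db_a = _db(["A", "B"], [_rxn("ra", [("A", 1)], [("B", 1)],
                                 ec_numbers=["1.2.3.4"])])
    db_b = _db(["A2", "B2"], [_rxn("rb", [("B2", 1)], [("A2", 1)],
                                   ec_numbers=["1.2.3.4"])])
    matches, _ = infer_reaction_matches(db_a, db_b, {"A": "A2", "B": "B2"})
    assert len(matches) == 1
    assert matches[0].cosine == pytest.approx(-1.0)


def test_zero_noise_recovery_exact(zero_twin):
    db_a, db_b, truth = zero_twin
    from concord.compound_matching import infer_compound_matches

    cpd_matches, _ = infer_compound_matches(db_a, db_b)
    links = {m.a_id: m.b_id for m in cpd_matches}
    matches, contras = infer_reaction_matches(db_a, db_b, links)
    assert {(m.a_id, m.b_id) for m in matches} == truth.reaction_pairs
    assert contras == []


def test_matches_one_to_one(default_pipeline):
    matches = default_pipeline.reaction_matches
    a_ids = [m.a_id for m in matches]
    b_ids = [m.b_id for m in matches]
    assert len(a_ids) == len(set(a_ids))
    assert len(b_ids) == len(set(b_ids))


def test_duplicate_reaction_rules():
    db = _db(
        ["A", "B", "C"],
        [
            _rxn("r1", [("A", 1), ("B", 1)], [("C", 1)]),
            _rxn("r2", [("C", 1)], [("A", 1), ("B", 1)]),  # reverse clause
            _rxn("r3", [("A", 2)], [("B", 1)]),
            _rxn("r4", [("A", 1)], [("B", 1)]),  # coefficients differ from r3
            _rxn("r5", [("A", 1)], [("B", 1)]),
            _rxn("r6", [("B", 1)], [("A", 1)]),
        ],
    )
    clusters = detect_duplicate_reactions(db)
    assert ["r1", "r2"] in clusters
    assert ["r4", "r5", "r6"] in clusters
    assert duplicate_reaction_count(db) == 3
    assert all("r3" not in c for c in clusters)


def test_duplicate_injections_counted():
    """With injected duplicates switched on (and other noise off), the
    duplicate count equals the number of injections."""
    from concord.synthetic_data import generate, zero_noise_config

    cfg = zero_noise_config(seed=55, duplicate_reaction_rate=0.05)
    db_a, db_b, truth = generate(cfg)
    for db in (db_a, db_b):
        injected = {
            (kept, dup)
            for d, kept, dup in truth.injected_duplicates
            if d == db.name
        }
        assert duplicate_reaction_count(db) == len(injected)
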