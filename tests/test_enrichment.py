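"""Fisher enrichment over the class ontology; uniqueness scoring."""

import math

import pytest

from concord.db_model import (
    CompoundRecord,
    PathwayDB,
    PathwayKind,
    PathwayRecord,
    PathwayClassNode,
    ReactionParticipant,
    ReactionRecord,
    Side,
    TaxonNode,
)
from concord.enrichment_analysis import (
    EnrichmentConfig,
    EnrichmentStatus,
    Tail,
    UniquenessConfig,
    class_reaction_sets,
    enrichment_depletion,
    hypergeom_tail,
    pathway_unique,
    taxon_uniqueness_table,
)


def _enumeration_tail(k, K, n, N, tail):
    """Exhaustive oracle: count the C(N, n) draws directly."""
    total = math.comb(N, n)
    count = 0
    for i in range(0, n + 1):
        if math.comb(K, i) == 0 or math.comb(N - K, n - i) == 0:
            continue
        hits = math.comb(K, i) * math.comb(N - K, n - i)
        if (tail is Tail.GE and i >= k) or (tail is Tail.LE and i <= k):
            count += hits
    return count / total


def test_hypergeom_examples():
    assert hypergeom_tail(0, 3, 2, 10, Tail.GE) == pytest.approx(1.0)
    assert hypergeom_tail(4, 5, 4, 10, Tail.GE) == pytest.approx(5 / 210)
    with pytest.raises(ValueError):
        hypergeom_tail(5, 3, 4, 10)


def test_hypergeom_matches_exhaustive_enumeration_small_margins():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    for tail in (Tail.GE, Tail.LE):
                        assert hypergeom_tail(k, K, n, N, tail) == pytest.approx(
                            _enumeration_tail(k, K, n, N, tail), abs=1e-10
                        ), (k, K, n, N, tail)


def test_tail_complement_identity():
    N, K, n = 12, 5, 6
    for k in range(1, n + 1):
        assert hypergeom_tail(k, K, n, N, Tail.GE) + hypergeom_tail(
            k - 1, K, n, N, Tail.LE
        ) == pytest.approx(1.0)


def _class_db(n_reactions=20, class_assignments=None, class_parents=None):
    db = PathwayDB()
    db.compounds["x"] = CompoundRecord("x")
    db.compounds["y"] = CompoundRecord("y")
    for i in range(n_reactions):
        db.reactions[f"r{i:02d}"] = ReactionRecord(
            f"r{i:02d}",
            [
                ReactionParticipant("x", 1, Side.LEFT),
                ReactionParticipant("y", i + 1, Side.RIGHT),
            ],
        )
    class_parents = class_parents or {}
    all_classes = (
        {cls for cls, _ in (class_assignments or {}).values()}
        | set(class_parents)
        | {p for ps in class_parents.values() for p in ps}
    )
    for cid in sorted(all_classes):
        db.classes[cid] = PathwayClassNode(
            cid, name=cid, parent_ids=class_parents.get(cid, [])
        )
    for pid, (cls, rids) in (class_assignments or {}).items():
        db.pathways[pid] = PathwayRecord(
            pid, PathwayKind.BASE, reaction_ids=rids, class_ids=[cls]
        )
    db.validate()
    return db


def test_class_reaction_sets_transitive_union():
    db = _class_db(
        class_assignments={
            "p1": ("child1", ["r00", "r01", "r02"]),
            "p2": ("child2", ["r02", "r03"]),
        },
        class_parents={"child1": ["root"], "child2": ["root"]},
    )
    sets = class_reaction_sets(db)
    assert sets["child1"] == {"r00", "r01", "r02"}
    assert sets["child2"] == {"r02", "r03"}
    # shared reaction counted once in the parent's union
    assert sets["root"] == {"r00", "r01", "r02", "r03"}


def test_cycle_in_ontology_is_error():
    db = _class_db()
    db.classes["c1"] = PathwayClassNode("c1", parent_ids=["c2"])
    db.classes["c2"] = PathwayClassNode("c2", parent_ids=["c1"])
    with pytest.raises(ValueError, match="cycle"):
        class_reaction_sets(db)


def test_enrichment_fixture_against_enumeration():
    """N=20 background, K=10 linked; a fully linked 6-reaction class among 2
    tested classes is enriched (p = C(10,6)/C(20,6), Bonferroni x2)."""
    db = _class_db(
        n_reactions=20,
        class_assignments={
            "p1": ("cls_hot", [f"r{i:02d}" for i in range(6)]),
            "p2": ("cls_rest", [f"r{i:02d}" for i in range(20)]),
        },
    )
    linked = {f"r{i:02d}" for i in range(10)}
    results = {
        r.class_id: r for r in enrichment_depletion(db, linked, EnrichmentConfig())
    }
    hot = results["cls_hot"]
    assert hot.n_reactions == 6 and hot.n_linked == 6
    expected_p = math.comb(10, 6) / math.comb(20, 6)
    assert hot.p_enrich == pytest.approx(expected_p)
    assert hot.p_adjusted == pytest.approx(2 * expected_p)
    assert hot.status is EnrichmentStatus.ENRICHED


def test_depletion_fixture_against_enumeration():
    db = _class_db(
        n_reactions=20,
        class_assignments={
            "p1": ("cls_cold", [f"r{i:02d}" for i in range(10, 16)]),
            "p2": ("cls_rest", [f"r{i:02d}" for i in range(20)]),
        },
    )
    linked = {f"r{i:02d}" for i in range(10)}
    results = {
        r.class_id: r for r in enrichment_depletion(db, linked, EnrichmentConfig())
    }
    cold = results["cls_cold"]
    assert cold.n_linked == 0
    expected_p = _enumeration_tail(0, 10, 6, 20, Tail.LE)
    assert cold.p_deplete == pytest.approx(expected_p)
    expected_status = (
        EnrichmentStatus.DEPLETED
        if 2 * expected_p <= 0.025
        else EnrichmentStatus.NS
    )
    assert cold.status is expected_status


def test_uniform_links_not_significant():
    db = _class_db(
        n_reactions=20,
        class_assignments={
            "p1": ("c1", [f"r{i:02d}" for i in range(0, 10)]),
            "p2": ("c2", [f"r{i:02d}" for i in range(10, 20)]),
        },
    )
    linked = {f"r{i:02d}" for i in range(0, 20, 2)}  # every class at 50%
    for r in enrichment_depletion(db, linked, EnrichmentConfig()):
        assert r.status is EnrichmentStatus.NS


def test_never_both_enriched_and_depleted(default_twin, default_pipeline):
    db_a, _, _ = default_twin
    linked = {a for a, _ in default_pipeline.reaction_pairs()}
    for r in enrichment_depletion(db_a, linked, EnrichmentConfig()):
        # the two one-sided tails overlap at P(X = k), so they sum to >= 1
        # and cannot both fall below any alpha < 0.5
        assert r.p_enrich + r.p_deplete >= 1.0 - 1e-9


# ---------------------------------------------------------------------------
# uniqueness


def _uniqueness_fixture(n_reactions, covered_by_best_q):
    db_a = PathwayDB(name="A")
    db_b = PathwayDB(name="B")
    for db, tag in ((db_a, "a"), (db_b, "b")):
        db.compounds["x" + tag] = CompoundRecord("x" + tag)
        db.compounds["y" + tag] = CompoundRecord("y" + tag)
    a_to_b = {}
    b_rids = []
    for i in range(n_reactions):
        ra, rb = f"ra{i}", f"rb{i}"
        db_a.reactions[ra] = ReactionRecord(
            ra,
            [
                ReactionParticipant("xa", 1, Side.LEFT),
                ReactionParticipant("ya", i + 1, Side.RIGHT),
            ],
        )
        db_b.reactions[rb] = ReactionRecord(
            rb,
            [
                ReactionParticipant("xb", 1, Side.LEFT),
                ReactionParticipant("yb", i + 1, Side.RIGHT),
            ],
        )
        a_to_b[ra] = rb
        b_rids.append(rb)
    db_a.pathways["pa"] = PathwayRecord(
        "pa", PathwayKind.BASE, reaction_ids=sorted(db_a.reactions)
    )
    db_b.pathways["qb"] = PathwayRecord(
        "qb", PathwayKind.BASE, reaction_ids=b_rids[:covered_by_best_q]
    )
    db_a.validate()
    db_b.validate()
    return db_a, db_b, a_to_b


@pytest.mark.parametrize(
    "n, covered, expected",
    [
        (4, 1, True),   # 0.25 <= 1/3
        (4, 2, False),  # 0.5 > 1/3
        (3, 1, True),   # exactly 1/3: inclusive boundary
    ],
)
def test_pathway_unique_boundary(n, covered, expected):
    db_a, db_b, a_to_b = _uniqueness_fixture(n, covered)
    assert pathway_unique(db_a, "pa", a_to_b, db_b) is expected


def test_pathway_unique_monotone_in_links():
    db_a, db_b, a_to_b = _uniqueness_fixture(4, 3)
    assert not pathway_unique(db_a, "pa", a_to_b, db_b)
    # removing links can only move toward uniqueness
    fewer = {k: v for k, v in list(a_to_b.items())[:1]}
    assert pathway_unique(db_a, "pa", fewer, db_b)


def test_taxon_uniqueness_rollup():
    db_a, db_b, a_to_b = _uniqueness_fixture(4, 1)
    db_a.taxa = {
        "1": TaxonNode("1", "root"),
        "2": TaxonNode("2", "child", parent_id="1"),
    }
    db_a.pathways["pa"].taxonomic_range = ["2"]
    db_a.validate()
    cfg = UniquenessConfig(min_taxon_pathways=1)
    rows = {r.taxon_id: r for r in taxon_uniqueness_table(db_a, a_to_b, db_b, cfg)}
    # the pathway rolls up from the child taxon to the root
    assert rows["1"].pathway_count == 1 and rows["1"].unique_count == 1
    assert rows["2"].pathway_count == 1
    assert rows["1"].pct_unique == 100.0
    # threshold excludes sparse taxa
    assert taxon_uniqueness_table(db_a, a_to_b, db_b, UniquenessConfig()) == []


def test_percent_unique_formula():
    assert round(100.0 * 878 / 1840, 1) == 47.7
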