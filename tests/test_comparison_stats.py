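"""Overlap tables, coverage statistics, report determinism."""

import pytest

from concord.comparison_stats import (
    CoverageClass,
    OverlapCategory,
    attribute_coverage,
    count_ratio,
    generate_report,
    jaccard,
    overlap_table,
    pathway_link_coverage,
    pathway_size_histogram,
    summary_stats,
)
from concord.correspondence import CorrespondenceSet, Link
from concord.db_model import (
    CompoundRecord,
    PathwayDB,
    PathwayKind,
    PathwayRecord,
    ReactionParticipant,
    ReactionRecord,
    Side,
)


def test_jaccard_basic():
    assert jaccard(5, 5, 5) == 1.0
    assert jaccard(4, 7, 0) == 0.0
    assert jaccard(3, 3, 2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        jaccard(0, 0, 0)
    with pytest.raises(ValueError):
        jaccard(2, 2, 3)


def test_jaccard_equals_brute_force_on_explicit_sets():
    import random

    rnd = random.Random(42)
    for _ in range(50):
        a = set(rnd.sample(range(40), rnd.randint(1, 20)))
        b = set(rnd.sample(range(40), rnd.randint(1, 20)))
        assert jaccard(len(a), len(b), len(a & b)) == pytest.approx(
            len(a & b) / len(a | b)
        )


def _five_compound_fixture():
    """Two tiny DBs with 2 compound links; counts checkable by hand."""
    db_a, db_b = PathwayDB(name="A"), PathwayDB(name="B")
    for cid in ("a1", "a2", "a3"):
        db_a.compounds[cid] = CompoundRecord(cid, common_name=cid)
    for cid in ("b1", "b2"):
        db_b.compounds[cid] = CompoundRecord(cid, common_name=cid)
    db_a.reactions["ra"] = ReactionRecord(
        "ra",
        [
            ReactionParticipant("a1", 1, Side.LEFT),
            ReactionParticipant("a2", 1, Side.RIGHT),
        ],
    )
    db_b.reactions["rb"] = ReactionRecord(
        "rb",
        [
            ReactionParticipant("b1", 1, Side.LEFT),
            ReactionParticipant("b2", 1, Side.RIGHT),
        ],
    )
    db_a.validate()
    db_b.validate()
    links = CorrespondenceSet(
        [
            Link("compound", "a1", "b1"),
            Link("compound", "a3", "b2"),
            Link("reaction", "ra", "rb"),
        ]
    )
    return db_a, db_b, links


def test_overlap_table_hand_enumeration():
    db_a, db_b, links = _five_compound_fixture()
    rows = {r.category: r for r in overlap_table(db_a, db_b, links, links)}
    all_cpd = rows[OverlapCategory.ALL_COMPOUNDS]
    assert (all_cpd.n_a, all_cpd.n_b, all_cpd.common) == (3, 2, 2)
    assert all_cpd.jaccard == pytest.approx(2 / 3)
    subs = rows[OverlapCategory.REACTION_SUBSTRATES]
    # a3 is not a substrate, so only the a1-b1 link counts
    assert (subs.n_a, subs.n_b, subs.common) == (2, 2, 1)
    rxns = rows[OverlapCategory.ALL_REACTIONS]
    assert (rxns.n_a, rxns.n_b, rxns.common) == (1, 1, 1)
    # no pathways: pathway scopes are empty with undefined jaccard
    assert rows[OverlapCategory.PATHWAY_REACTIONS].jaccard is None


def test_overlap_full_and_zero_sharing(zero_twin):
    db_a, db_b, truth = zero_twin
    links = CorrespondenceSet(
        [Link("compound", a, b) for a, b in sorted(truth.compound_pairs)]
        + [Link("reaction", a, b) for a, b in sorted(truth.reaction_pairs)]
    )
    rows = {r.category: r for r in overlap_table(db_a, db_b, links, links)}
    row = rows[OverlapCategory.ALL_COMPOUNDS]
    assert row.common == row.n_a == row.n_b
    assert row.jaccard == pytest.approx(1.0)
    empty = CorrespondenceSet()
    rows0 = {r.category: r for r in overlap_table(db_a, db_b, empty, empty)}
    assert rows0[OverlapCategory.ALL_COMPOUNDS].common == 0
    assert rows0[OverlapCategory.ALL_COMPOUNDS].jaccard == pytest.approx(0.0)


def test_common_never_exceeds_link_count(default_twin, default_pipeline):
    db_a, db_b, _ = default_twin
    cs = default_pipeline.correspondences()
    for row in overlap_table(db_a, db_b, cs, cs):
        n_links = len(
            cs.pairs(
                "reaction"
                if row.category
                in (OverlapCategory.ALL_REACTIONS, OverlapCategory.PATHWAY_REACTIONS)
                else "compound"
            )
        )
        assert row.common <= n_links


def test_attribute_coverage_threshold():
    db = PathwayDB()
    for i in range(200):
        rec = CompoundRecord(f"c{i:03d}", common_name=f"name{i}")
        if i < 99:
            rec.attributes["RARE"] = ["v"]
        rec.attributes["EVERYWHERE"] = ["v"]
        db.compounds[rec.id] = rec
    cov = attribute_coverage(db, min_objects=100)
    attrs = set(cov[cov.entity == "compound"].attribute)
    assert "EVERYWHERE" in attrs and "RARE" not in attrs
    cov1 = attribute_coverage(db, min_objects=1)
    attrs1 = dict(
        zip(
            cov1[cov1.entity == "compound"].attribute,
            cov1[cov1.entity == "compound"]["count"],
        )
    )
    assert attrs1["RARE"] == 99 and attrs1["EVERYWHERE"] == 200


def test_summary_stats_conventions():
    db = PathwayDB()
    db.compounds["c1"] = CompoundRecord(
        "c1", common_name="x", comment="abcde"
    )
    db.compounds["c2"] = CompoundRecord(
        "c2", common_name="y", synonyms=["y1", "y2"]
    )
    for i in range(8):
        db.compounds[f"f{i}"] = CompoundRecord(f"f{i}", common_name=str(i))
    stats = summary_stats(db)
    # comment length averaged over commented objects only
    assert stats["mean_compound_comment_length"] == 5.0
    assert stats["compounds_with_comments"] == 1
    # names averaged over all compounds: (1 + 3 + 8) / 10
    assert stats["mean_names_per_compound"] == pytest.approx(1.2)
    empty = summary_stats(PathwayDB())
    assert empty["mean_names_per_compound"] is None


def test_pathway_size_histogram(tiny_db):
    bins, applied, warnings = pathway_size_histogram(tiny_db, PathwayKind.BASE)
    assert bins == {2: 1}
    bins, applied, warnings = pathway_size_histogram(
        tiny_db, PathwayKind.BASE, exclude=["P1", "ghost"]
    )
    assert bins == {}
    assert applied == ["P1"]
    assert warnings and "ghost" in warnings[0]


def test_single_reaction_pathway_fraction():
    db = PathwayDB()
    db.compounds["a"] = CompoundRecord("a")
    db.compounds["b"] = CompoundRecord("b")
    db.reactions["r1"] = ReactionRecord(
        "r1",
        [
            ReactionParticipant("a", 1, Side.LEFT),
            ReactionParticipant("b", 1, Side.RIGHT),
        ],
    )
    db.reactions["r2"] = ReactionRecord(
        "r2",
        [
            ReactionParticipant("b", 1, Side.LEFT),
            ReactionParticipant("a", 1, Side.RIGHT),
        ],
    )
    for i, rids in enumerate((["r1"], ["r2"], ["r1", "r2"])):
        db.pathways[f"p{i}"] = PathwayRecord(
            f"p{i}", PathwayKind.BASE, reaction_ids=rids
        )
    db.validate()
    bins, _, _ = pathway_size_histogram(db, PathwayKind.BASE)
    assert bins == {1: 2, 2: 1}
    assert bins[1] / sum(bins.values()) == pytest.approx(2 / 3)


def test_pathway_link_coverage_classes(tiny_db):
    cov = pathway_link_coverage(tiny_db, {"R1", "R2", "R3"})
    assert cov.per_pathway == {"P1": CoverageClass.ALL, "SP": CoverageClass.ALL}
    cov = pathway_link_coverage(tiny_db, set())
    assert set(cov.per_pathway.values()) == {CoverageClass.NONE}
    assert cov.unlinked_pathway_reactions == 3
    cov = pathway_link_coverage(tiny_db, {"R1"})
    assert cov.per_pathway["P1"] == CoverageClass.SOME
    assert cov.counts[CoverageClass.SOME] == 2
    # the three classes partition the pathway set
    assert sum(cov.counts.values()) == len(tiny_db.pathways)


def test_count_ratio():
    assert count_ratio(20, 2) == 10.0
    with pytest.raises(ValueError):
        count_ratio(1, 0)


def test_report_runs_and_is_deterministic(tmp_path, default_twin, default_pipeline):
    db_a, db_b, _ = default_twin
    cs = default_pipeline.correspondences()
    generate_report(db_a, db_b, cs, cs, tmp_path / "r1", min_objects=10)
    generate_report(db_a, db_b, cs, cs, tmp_path / "r2", min_objects=10)
    files = [
        "overlap.tsv", "attributes_a.tsv", "attributes_b.tsv", "quality.tsv",
        "pathway_sizes_a.tsv", "pathway_sizes_b.tsv", "coverage.tsv",
        "summary.md",
    ]
    for f in files:
        assert (tmp_path / "r1" / f).is_file()
        assert (tmp_path / "r1" / f).read_bytes() == (
            tmp_path / "r2" / f
        ).read_bytes()
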