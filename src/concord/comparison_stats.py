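"""Side-by-side content statistics for a pair of pathway databases.

Produces the comparison tables of a database concordance report: overlap
counts with Jaccard coefficients for compound and reaction categories,
attribute-coverage tables (attributes populated on at least ``min_objects``
records), per-database content means, pathway-size histograms, a
per-pathway link-coverage classification (all / some / none of a pathway's
reactions linked to the other database), and a consolidated deterministic
TSV + markdown report bundle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .compound_matching import duplicate_compound_count
from .correspondence import CorrespondenceSet
from .db_model import (
    PathwayDB,
    PathwayKind,
    SubstrateScope,
    pathway_reaction_set,
    substrate_set,
    transitive_reaction_ids,
)
from .reaction_matching import duplicate_reaction_count
from .reaction_quality import unbalanced_counts


class OverlapCategory(str, Enum):
    ALL_COMPOUNDS = "ALL_COMPOUNDS"
    REACTION_SUBSTRATES = "REACTION_SUBSTRATES"
    PATHWAY_REACTION_SUBSTRATES = "PATHWAY_REACTION_SUBSTRATES"
    ALL_REACTIONS = "ALL_REACTIONS"
    PATHWAY_REACTIONS = "PATHWAY_REACTIONS"


@dataclass
class OverlapRow:
    category: OverlapCategory
    n_a: int
    n_b: int
    common: int
    jaccard: float | None
    # per-pathway-kind sub-scope counts, e.g. {"BASE": 12, "SUPER": 15}
    n_a_by_kind: dict[str, int] = field(default_factory=dict)
    n_b_by_kind: dict[str, int] = field(default_factory=dict)


def jaccard(n_a: int, n_b: int, common: int) -> float:
    """|A ∩ B| / |A ∪ B| from set sizes and intersection count."""
    if common > min(n_a, n_b):
        raise ValueError("common exceeds a set size")
    union = n_a + n_b - common
    if union <= 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return common / union


def _common(
    pairs: set[tuple[str, str]], set_a: set[str], set_b: set[str]
) -> int:
    """Number of link pairs with both ends inside the category sets."""
    return sum(1 for a, b in pairs if a in set_a and b in set_b)


def overlap_table(
    db_a: PathwayDB,
    db_b: PathwayDB,
    compound_links: CorrespondenceSet,
    reaction_links: CorrespondenceSet,
) -> list[OverlapRow]:
    cpairs = compound_links.pairs("compound")
    rpairs = reaction_links.pairs("reaction")
    rows: list[OverlapRow] = []

    def add(category, set_a, set_b, pairs, by_kind=False, substrates=True):
        n_a, n_b, common = len(set_a), len(set_b), _common(pairs, set_a, set_b)
        j = jaccard(n_a, n_b, common) if (n_a + n_b) else None
        row = OverlapRow(category, n_a, n_b, common, j)
        if by_kind:
            for kind in PathwayKind:
                if substrates:
                    row.n_a_by_kind[kind.value] = len(
                        substrate_set(db_a, SubstrateScope.PATHWAY_REACTIONS, kind)
                    )
                    row.n_b_by_kind[kind.value] = len(
                        substrate_set(db_b, SubstrateScope.PATHWAY_REACTIONS, kind)
                    )
                else:
                    row.n_a_by_kind[kind.value] = len(pathway_reaction_set(db_a, kind))
                    row.n_b_by_kind[kind.value] = len(pathway_reaction_set(db_b, kind))
        rows.append(row)

    add(
        OverlapCategory.ALL_COMPOUNDS,
        set(db_a.compounds),
        set(db_b.compounds),
        cpairs,
    )
    add(
        OverlapCategory.REACTION_SUBSTRATES,
        substrate_set(db_a, SubstrateScope.ALL_REACTIONS),
        substrate_set(db_b, SubstrateScope.ALL_REACTIONS),
        cpairs,
    )
    add(
        OverlapCategory.PATHWAY_REACTION_SUBSTRATES,
        substrate_set(db_a, SubstrateScope.PATHWAY_REACTIONS),
        substrate_set(db_b, SubstrateScope.PATHWAY_REACTIONS),
        cpairs,
        by_kind=True,
    )
    add(
        OverlapCategory.ALL_REACTIONS,
        set(db_a.reactions),
        set(db_b.reactions),
        rpairs,
    )
    add(
        OverlapCategory.PATHWAY_REACTIONS,
        pathway_reaction_set(db_a),
        pathway_reaction_set(db_b),
        rpairs,
        by_kind=True,
        substrates=False,
    )
    return rows


# ---------------------------------------------------------------------------
# Attribute coverage


def _compound_attribute_values(rec) -> dict[str, list]:
    out = dict(rec.attributes)
    if rec.common_name:
        out["COMMON-NAME"] = [rec.common_name]
    if rec.synonyms:
        out["SYNONYMS"] = rec.synonyms
    if rec.formula is not None:
        out["FORMULA"] = [rec.formula]
    if rec.inchi is not None:
        out["INCHI"] = [rec.inchi]
    if rec.fingerprint is not None:
        out["FINGERPRINT"] = [rec.fingerprint]
    if rec.links:
        out["DBLINK"] = list(rec.links)
    if rec.comment is not None:
        out["COMMENT"] = [rec.comment]
    return out


def _reaction_attribute_values(rec) -> dict[str, list]:
    out = dict(rec.attributes)
    if rec.ec_numbers:
        out["EC-NUMBER"] = rec.ec_numbers
    if rec.uniprot_accessions:
        out["UNIPROT"] = rec.uniprot_accessions
    if rec.activity_names:
        out["ACTIVITY-NAME"] = rec.activity_names
    if rec.spontaneous is not None:
        out["SPONTANEOUS?"] = [rec.spontaneous]
    if rec.links:
        out["DBLINK"] = list(rec.links)
    if rec.comment is not None:
        out["COMMENT"] = [rec.comment]
    return out


def _pathway_attribute_values(rec) -> dict[str, list]:
    out = dict(rec.attributes)
    if rec.class_ids:
        out["IN-CLASS"] = rec.class_ids
    if rec.taxonomic_range:
        out["TAXONOMIC-RANGE"] = rec.taxonomic_range
    if rec.subpathway_ids:
        out["SUBPATHWAY"] = rec.subpathway_ids
    if rec.links:
        out["DBLINK"] = list(rec.links)
    if rec.comment is not None:
        out["COMMENT"] = [rec.comment]
    return out


_ENTITY_EXTRACTORS = {
    "compound": ("compounds", _compound_attribute_values),
    "reaction": ("reactions", _reaction_attribute_values),
    "pathway": ("pathways", _pathway_attribute_values),
}


def attribute_coverage(db: PathwayDB, min_objects: int = 100) -> pd.DataFrame:
    """Per entity kind, the attributes populated on >= ``min_objects``
    records, with the number of records carrying at least one value; sorted
    by descending count then name."""
    rows = []
    for kind, (collection_name, extract) in _ENTITY_EXTRACTORS.items():
        counts: Counter = Counter()
        for rec in getattr(db, collection_name).values():
            for attr, values in extract(rec).items():
                if values:
                    counts[attr] += 1
        for attr, count in counts.items():
            if count >= min_objects:
                rows.append({"entity": kind, "attribute": attr, "count": count})
    df = pd.DataFrame(rows, columns=["entity", "attribute", "count"])
    return df.sort_values(
        ["entity", "count", "attribute"], ascending=[True, False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Content means


def summary_stats(db: PathwayDB) -> dict[str, float | int | None]:
    """Arithmetic means of the content comparison tables.

    Comment lengths are averaged over commented objects only; names and
    associated reactions/pathways are averaged over all compounds; per-kind
    pathway sizes use transitive reaction sets.
    """
    out: dict[str, float | int | None] = {}
    n_cpd = len(db.compounds)
    out["n_compounds"] = n_cpd
    out["n_reactions"] = len(db.reactions)
    out["n_pathways"] = len(db.pathways)
    out["compounds_with_structures"] = sum(
        1 for c in db.compounds.values() if c.inchi is not None
    )

    def mean(values: list[float]) -> float | None:
        return sum(values) / len(values) if values else None

    out["mean_names_per_compound"] = mean(
        [len(c.names()) for c in db.compounds.values()]
    )
    cpd_comments = [len(c.comment) for c in db.compounds.values() if c.comment]
    out["compounds_with_comments"] = len(cpd_comments)
    out["mean_compound_comment_length"] = mean(cpd_comments)
    rxn_comments = [len(r.comment) for r in db.reactions.values() if r.comment]
    out["reactions_with_comments"] = len(rxn_comments)
    out["mean_reaction_comment_length"] = mean(rxn_comments)

    assoc_rxns: Counter = Counter()
    for rxn in db.reactions.values():
        for cid in rxn.compound_ids():
            assoc_rxns[cid] += 1
    out["mean_associated_reactions_per_compound"] = (
        mean([assoc_rxns.get(c, 0) for c in db.compounds]) if n_cpd else None
    )
    assoc_pwys: Counter = Counter()
    for pid in db.pathways:
        for rid in transitive_reaction_ids(db, pid):
            rxn = db.reactions.get(rid)
            if rxn:
                for cid in rxn.compound_ids():
                    assoc_pwys[cid] += 1
    out["mean_associated_pathways_per_compound"] = (
        mean([assoc_pwys.get(c, 0) for c in db.compounds]) if n_cpd else None
    )

    for kind in PathwayKind:
        pids = [p for p, rec in db.pathways.items() if rec.kind is kind]
        sizes = [len(transitive_reaction_ids(db, p)) for p in pids]
        cpd_sizes = []
        for p in pids:
            subs: set[str] = set()
            for rid in transitive_reaction_ids(db, p):
                rxn = db.reactions.get(rid)
                if rxn:
                    subs.update(rxn.compound_ids())
            cpd_sizes.append(len(subs))
        tag = kind.value.lower()
        out[f"n_{tag}_pathways"] = len(pids)
        out[f"mean_reactions_per_{tag}_pathway"] = mean(sizes)
        out[f"mean_compounds_per_{tag}_pathway"] = mean(cpd_sizes)
    return out


# ---------------------------------------------------------------------------
# Pathway size histograms and link coverage


def pathway_size_histogram(
    db: PathwayDB,
    kind: PathwayKind,
    bin_width: int = 1,
    exclude: list[str] | None = None,
) -> tuple[dict[int, int], list[str], list[str]]:
    """(bins, excluded ids applied, warnings) of pathway reaction counts.

    Bins are keyed by the lower edge (``size // bin_width * bin_width``).
    Unknown excluded ids produce warnings, not errors.
    """
    exclude = list(exclude or [])
    warnings = [f"unknown excluded pathway id {e}" for e in exclude if e not in db.pathways]
    applied = [e for e in exclude if e in db.pathways]
    bins: Counter = Counter()
    for pid, rec in db.pathways.items():
        if rec.kind is not kind or pid in applied:
            continue
        size = len(transitive_reaction_ids(db, pid))
        bins[(size // bin_width) * bin_width] += 1
    return dict(sorted(bins.items())), applied, warnings


class CoverageClass(str, Enum):
    ALL = "ALL"
    SOME = "SOME"
    NONE = "NONE"


@dataclass
class CoverageClassification:
    per_pathway: dict[str, CoverageClass]
    counts: dict[CoverageClass, int]
    #: pathway reactions of this DB with no link to the other DB
    unlinked_pathway_reactions: int


def pathway_link_coverage(
    db: PathwayDB,
    linked_reaction_ids: set[str],
    kind: PathwayKind | None = None,
) -> CoverageClassification:
    """Classify each pathway by how many of its reactions are linked."""
    per: dict[str, CoverageClass] = {}
    for pid, rec in sorted(db.pathways.items()):
        if kind is not None and rec.kind is not kind:
            continue
        rids = transitive_reaction_ids(db, pid)
        if not rids:
            per[pid] = CoverageClass.NONE
            continue
        n_linked = len(rids & linked_reaction_ids)
        if n_linked == len(rids):
            per[pid] = CoverageClass.ALL
        elif n_linked == 0:
            per[pid] = CoverageClass.NONE
        else:
            per[pid] = CoverageClass.SOME
    counts = {c: 0 for c in CoverageClass}
    for c in per.values():
        counts[c] += 1
    unlinked = len(pathway_reaction_set(db, kind) - linked_reaction_ids)
    return CoverageClassification(per, counts, unlinked)


# ---------------------------------------------------------------------------
# Consolidated report


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def generate_report(
    db_a: PathwayDB,
    db_b: PathwayDB,
    compound_links: CorrespondenceSet,
    reaction_links: CorrespondenceSet,
    out_dir: str | Path,
    min_objects: int = 100,
) -> Path:
    """Write the full comparison bundle; two runs are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = overlap_table(db_a, db_b, compound_links, reaction_links)
    with open(out / "overlap.tsv", "w", encoding="utf-8") as fh:
        fh.write("category\tn_a\tn_b\tcommon\tjaccard\tn_a_by_kind\tn_b_by_kind\n")
        for r in rows:
            j = "NA" if r.jaccard is None else f"{r.jaccard:.2f}"
            ka = ";".join(f"{k}={v}" for k, v in sorted(r.n_a_by_kind.items()))
            kb = ";".join(f"{k}={v}" for k, v in sorted(r.n_b_by_kind.items()))
            fh.write(
                f"{r.category.value}\t{r.n_a}\t{r.n_b}\t{r.common}\t{j}\t{ka}\t{kb}\n"
            )

    for tag, db in (("a", db_a), ("b", db_b)):
        attribute_coverage(db, min_objects).to_csv(
            out / f"attributes_{tag}.tsv", sep="\t", index=False
        )
        with open(out / f"pathway_sizes_{tag}.tsv", "w", encoding="utf-8") as fh:
            fh.write("kind\tsize\tcount\n")
            for kind in PathwayKind:
                bins, _, _ = pathway_size_histogram(db, kind)
                for size, count in bins.items():
                    fh.write(f"{kind.value}\t{size}\t{count}\n")

    with open(out / "quality.tsv", "w", encoding="utf-8") as fh:
        fh.write("db\treactions\tduplicate_compounds\tduplicate_reactions\t"
                 "unbalanced_no_h\tunbalanced_with_h\tskipped\thigh_quality\n")
        for db in (db_a, db_b):
            no_h, with_h, skipped = unbalanced_counts(db)
            dup_r = duplicate_reaction_count(db)
            hq = len(db.reactions) - dup_r - with_h
            fh.write(
                f"{db.name}\t{len(db.reactions)}\t{duplicate_compound_count(db)}\t"
                f"{dup_r}\t{no_h}\t{with_h}\t{skipped}\t{hq}\n"
            )

    a_linked = {a for a, _ in reaction_links.pairs("reaction")}
    b_linked = {b for _, b in reaction_links.pairs("reaction")}
    with open(out / "coverage.tsv", "w", encoding="utf-8") as fh:
        fh.write("db\tkind\tall\tsome\tnone\tunlinked_pathway_reactions\n")
        for db, linked in ((db_a, a_linked), (db_b, b_linked)):
            for kind in PathwayKind:
                cov = pathway_link_coverage(db, linked, kind)
                fh.write(
                    f"{db.name}\t{kind.value}\t{cov.counts[CoverageClass.ALL]}\t"
                    f"{cov.counts[CoverageClass.SOME]}\t{cov.counts[CoverageClass.NONE]}\t"
                    f"{cov.unlinked_pathway_reactions}\n"
                )

    stats_a = summary_stats(db_a)
    stats_b = summary_stats(db_b)
    lines = ["# Database comparison summary", ""]
    lines.append(f"Databases: {db_a.name} vs {db_b.name}")
    lines.append("")
    lines.append("## Content means")
    lines.append("")
    lines.append(f"| quantity | {db_a.name} | {db_b.name} |")
    lines.append("|---|---|---|")
    for key in sorted(set(stats_a) | set(stats_b)):
        lines.append(
            f"| {key} | {_fmt(stats_a.get(key))} | {_fmt(stats_b.get(key))} |"
        )
    lines.append("")
    lines.append("## Ratios")
    lines.append("")

    def ratio(x, y) -> str:
        if not x or not y:
            return "NA"
        return f"{x / y:.1f}"

    lines.append(
        f"- base-pathway count ratio ({db_a.name}:{db_b.name}): "
        f"{ratio(stats_a['n_base_pathways'], stats_b['n_base_pathways'])}"
    )
    lines.append(
        f"- reaction count ratio: "
        f"{ratio(stats_a['n_reactions'], stats_b['n_reactions'])}"
    )
    ra = stats_a["mean_reactions_per_base_pathway"]
    rb = stats_b["mean_reactions_per_base_pathway"]
    lines.append(f"- reactions-per-base-pathway ratio: {ratio(rb, ra)} (B:A)")
    lines.append("")
    lines.append("## Links")
    lines.append("")
    lines.append(f"- compound links: {len(compound_links.pairs('compound'))}")
    lines.append(f"- reaction links: {len(reaction_links.pairs('reaction'))}")
    (out / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def count_ratio(n_a: int | float, n_b: int | float, digits: int = 1) -> float:
    """Simple rounded ratio line, e.g. 1846 base pathways / 179 modules -> 10.3."""
    if n_b == 0:
        raise ValueError("ratio undefined")
    return round(n_a / n_b, digits)
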