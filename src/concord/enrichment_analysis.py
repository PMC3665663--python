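"""Enrichment/depletion of cross-database reaction links over the pathway
class ontology, plus pathway- and taxon-level uniqueness scoring.

For every pathway class the reactions contained in its pathway instances
(transitively through subclasses and subpathways) form a draw of size ``n``
from the background of ``N`` pathway reactions, of which ``K`` are linked to
the other database.  One-sided Fisher exact tails of the hypergeometric
distribution in each direction, Bonferroni-corrected over the classes
tested, flag classes with significantly more (``ENRICHED``) or fewer
(``DEPLETED``) linked reactions than chance at the configured alpha
(default 0.025).

A pathway is *unique* to its database when no single pathway of the other
database contains the linked counterparts of more than one third (inclusive
by default) of its reactions; uniqueness fractions are then aggregated per
taxon over the taxonomic ranges of base pathways, restricted to taxa with
at least ``min_taxon_pathways`` pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy import stats

from .db_model import (
    PathwayDB,
    PathwayKind,
    PathwayRecord,
    pathway_reaction_set,
    transitive_reaction_ids,
)


class Tail(str, Enum):
    GE = "GE"
    LE = "LE"


class EnrichmentStatus(str, Enum):
    ENRICHED = "ENRICHED"
    DEPLETED = "DEPLETED"
    NS = "NS"


@dataclass
class EnrichmentConfig:
    alpha: float = 0.025
    correction: str = "BONFERRONI"  # or "NONE"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("BONFERRONI", "NONE"):
            raise ValueError("correction must be BONFERRONI or NONE")


@dataclass
class ClassEnrichmentResult:
    class_id: str
    class_size_pathways: int
    n_reactions: int
    n_linked: int
    p_enrich: float
    p_deplete: float
    p_adjusted: float
    status: EnrichmentStatus


@dataclass
class UniquenessConfig:
    max_linked_fraction: float = 1.0 / 3.0  # inclusive
    min_taxon_pathways: int = 50

    def __post_init__(self):
        if not (0.0 <= self.max_linked_fraction <= 1.0):
            raise ValueError("max_linked_fraction must lie in [0, 1]")


def hypergeom_tail(k: int, K: int, n: int, N: int, tail: Tail = Tail.GE) -> float:
    """Exact Fisher tail for X ~ Hypergeometric(N, K, n).

    GE gives P(X >= k), LE gives P(X <= k); computed via the survival/cdf
    functions of :mod:`scipy.stats`, which work in log space internally.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent margins k={k} K={K} n={n} N={N}")
    dist = stats.hypergeom(N, K, n)
    if tail is Tail.GE:
        return float(min(1.0, dist.sf(k - 1)))
    return float(min(1.0, dist.cdf(k)))


def class_descendants(db: PathwayDB) -> dict[str, set[str]]:
    """class id -> {itself plus all transitive subclasses}; cycle -> error."""
    children: dict[str, set[str]] = {c: set() for c in db.classes}
    for cid, node in db.classes.items():
        for parent in node.parent_ids:
            if parent in children:
                children[parent].add(cid)
    out: dict[str, set[str]] = {}

    def collect(cid: str, seen: tuple[str, ...]) -> set[str]:
        if cid in seen:
            raise ValueError(f"cycle in class ontology at {cid}")
        if cid in out:
            return out[cid]
        acc = {cid}
        for ch in children[cid]:
            acc |= collect(ch, seen + (cid,))
        out[cid] = acc
        return acc

    for cid in sorted(db.classes):
        collect(cid, ())
    return out


def class_reaction_sets(db: PathwayDB) -> dict[str, set[str]]:
    """Reactions contained in a class's pathway instances, transitively
    through subclasses (and subpathways)."""
    desc = class_descendants(db)
    by_class: dict[str, set[str]] = {c: set() for c in db.classes}
    pwy_reactions = {
        pid: transitive_reaction_ids(db, pid) for pid in db.pathways
    }
    membership: dict[str, set[str]] = {c: set() for c in db.classes}
    for pid, rec in db.pathways.items():
        for cid in rec.class_ids:
            if cid in membership:
                membership[cid].add(pid)
    for cid in db.classes:
        for sub in desc[cid]:
            for pid in membership[sub]:
                by_class[cid] |= pwy_reactions[pid]
    return by_class


def enrichment_depletion(
    db: PathwayDB,
    linked_reaction_ids: set[str],
    cfg: EnrichmentConfig | None = None,
) -> list[ClassEnrichmentResult]:
    """Per-class Fisher enrichment/depletion of linked reactions.

    Background: all pathway reactions of ``db``; classes with empty reaction
    sets are not tested (and do not count toward the Bonferroni factor).
    """
    cfg = cfg or EnrichmentConfig()
    background = pathway_reaction_set(db)
    N = len(background)
    K = len(background & linked_reaction_ids)
    sets = class_reaction_sets(db)
    desc = class_descendants(db)
    membership: dict[str, int] = {}
    for cid in db.classes:
        pids = {
            pid
            for pid, rec in db.pathways.items()
            if set(rec.class_ids) & desc[cid]
        }
        membership[cid] = len(pids)
    tested = [c for c in sorted(sets) if sets[c]]
    m = len(tested)
    results: list[ClassEnrichmentResult] = []
    for cid in tested:
        rxns = sets[cid] & background
        n = len(rxns)
        k = len(rxns & linked_reaction_ids)
        if n == 0 or N == 0:
            continue
        p_enrich = hypergeom_tail(k, K, n, N, Tail.GE)
        p_deplete = hypergeom_tail(k, K, n, N, Tail.LE)
        if cfg.correction == "BONFERRONI":
            adj_enrich = min(1.0, p_enrich * m)
            adj_deplete = min(1.0, p_deplete * m)
        else:
            adj_enrich, adj_deplete = p_enrich, p_deplete
        if adj_enrich <= cfg.alpha:
            status, p_adj = EnrichmentStatus.ENRICHED, adj_enrich
        elif adj_deplete <= cfg.alpha:
            status, p_adj = EnrichmentStatus.DEPLETED, adj_deplete
        else:
            status, p_adj = EnrichmentStatus.NS, min(adj_enrich, adj_deplete)
        results.append(
            ClassEnrichmentResult(
                class_id=cid,
                class_size_pathways=membership[cid],
                n_reactions=n,
                n_linked=k,
                p_enrich=p_enrich,
                p_deplete=p_deplete,
                p_adjusted=p_adj,
                status=status,
            )
        )
    return results


def pathway_unique(
    db: PathwayDB,
    pathway: PathwayRecord | str,
    a_to_b: dict[str, str],
    other_db: PathwayDB,
    cfg: UniquenessConfig | None = None,
) -> bool:
    """Is this pathway unique to ``db``?

    For every other-database pathway Q, the coverage of this pathway by Q is
    the fraction of its reactions whose linked counterpart belongs to Q; the
    pathway is unique when the best coverage is at most
    ``max_linked_fraction`` (inclusive).
    """
    cfg = cfg or UniquenessConfig()
    if isinstance(pathway, str):
        pathway_rec = db.pathways[pathway]
    else:
        pathway_rec = pathway
    rids = transitive_reaction_ids(db, pathway_rec.id)
    if not rids:
        raise ValueError(f"pathway {pathway_rec.id} has no reactions")
    linked = {r: a_to_b[r] for r in rids if r in a_to_b}
    if not linked:
        return True
    best = 0.0
    counterparts = set(linked.values())
    for qid in other_db.pathways:
        q_rxns = transitive_reaction_ids(other_db, qid)
        cov = len(counterparts & q_rxns) / len(rids)
        best = max(best, cov)
    # add a small epsilon-free inclusive comparison via fractions of counts
    return best <= cfg.max_linked_fraction + 1e-12


@dataclass
class TaxonUniquenessRow:
    taxon_id: str
    name: str
    pathway_count: int
    unique_count: int
    pct_unique: float


def taxon_uniqueness_table(
    db: PathwayDB,
    a_to_b: dict[str, str],
    other_db: PathwayDB,
    cfg: UniquenessConfig | None = None,
) -> list[TaxonUniquenessRow]:
    """Uniqueness of base pathways aggregated over the taxonomy.

    A base pathway counts under taxon t when any taxon of its taxonomic
    range equals t or descends from t; only taxa with at least
    ``min_taxon_pathways`` pathways are reported.  Percentages are rounded
    to one decimal.
    """
    cfg = cfg or UniquenessConfig()
    # ancestors including self, per taxon
    ancestors: dict[str, list[str]] = {}
    for tid in db.taxa:
        chain = []
        cur: str | None = tid
        while cur is not None and cur in db.taxa and cur not in chain:
            chain.append(cur)
            cur = db.taxa[cur].parent_id
        ancestors[tid] = chain
    counts: dict[str, int] = {t: 0 for t in db.taxa}
    uniques: dict[str, int] = {t: 0 for t in db.taxa}
    for pid, rec in sorted(db.pathways.items()):
        if rec.kind is not PathwayKind.BASE or not rec.reaction_ids:
            continue
        is_unique = pathway_unique(db, rec, a_to_b, other_db, cfg)
        covered: set[str] = set()
        for tid in rec.taxonomic_range:
            covered.update(ancestors.get(tid, []))
        for t in covered:
            counts[t] += 1
            if is_unique:
                uniques[t] += 1
    rows = [
        TaxonUniquenessRow(
            taxon_id=t,
            name=db.taxa[t].name,
            pathway_count=counts[t],
            unique_count=uniques[t],
            pct_unique=round(100.0 * uniques[t] / counts[t], 1),
        )
        for t in sorted(db.taxa)
        if counts[t] >= cfg.min_taxon_pathways
    ]
    rows.sort(key=lambda r: (-r.pathway_count, r.taxon_id))
    return rows
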