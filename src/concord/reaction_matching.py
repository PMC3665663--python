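"""Reaction correspondence inference via stoichiometric cosine similarity.

Both databases' reactions are embedded as columns of one joint
stoichiometric matrix: each distinct compound identity gets a row (compounds
linked across the databases share a row; unlinked compounds get private
rows), reactant coefficients enter negative, product coefficients positive.
A reaction pair is proposed when the absolute cosine similarity of its two
columns is strictly above the threshold (default 0.6; the absolute value
absorbs reaction orientation) *and* at least one annotation feature fires:

- ``UNIPROT``: at least one UniProt accession in common;
- ``EC``: an exact (full-string) Enzyme Commission number in common;
- ``ACTIVITY_NAME``: an enzymatic-activity name matching after
  canonicalization (case/punctuation stripped).

Contradictions (a reaction with two or more distinct proposed partners) void
every implicated pair.  Finally, an EC fallback links remaining unmatched
reactions when an identical EC number maps exactly one unmatched reaction of
one database to exactly one of the other.

Duplicate detection within one database: two reactions are duplicates when
their (reactant multiset, product multiset) signatures are equal, directly
or after reversing one of them; coefficients participate in the multisets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .compound_matching import canonicalize_name
from .correspondence import CorrespondenceSet, Link
from .db_model import PathwayDB, ReactionRecord, Side

UNIPROT = "UNIPROT"
EC = "EC"
ACTIVITY_NAME = "ACTIVITY_NAME"
ALL_REACTION_FEATURES = frozenset({UNIPROT, EC, ACTIVITY_NAME})


@dataclass
class ReactionMatchConfig:
    cosine_threshold: float = 0.6  # strict >, applied to |cos|
    features_enabled: frozenset[str] = ALL_REACTION_FEATURES
    ec_fallback: bool = True

    def __post_init__(self):
        if not (0.0 <= self.cosine_threshold <= 1.0):
            raise ValueError("cosine_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ReactionMatch:
    a_id: str
    b_id: str
    cosine: float | None
    features: frozenset[str]
    via_ec_fallback: bool = False
    source: str = "inferred"


@dataclass
class ReactionContradiction:
    reaction_id: str
    db: str
    partners: tuple[str, ...]


class StoichiometricMatrix:
    """Joint sparse stoichiometric matrix over two databases.

    Rows are compound identities (linked pairs merge), columns are
    db-qualified reactions; values are signed integer coefficients.
    """

    def __init__(self):
        self.row_index: dict[tuple[str, str], int] = {}
        self.columns: dict[tuple[str, str], dict[int, int]] = {}

    def _row(self, key: tuple[str, str]) -> int:
        if key not in self.row_index:
            self.row_index[key] = len(self.row_index)
        return self.row_index[key]

    def column(self, db_tag: str, reaction_id: str) -> dict[int, int]:
        return self.columns[(db_tag, reaction_id)]


def build_stoich_matrix(
    db_a: PathwayDB,
    db_b: PathwayDB,
    compound_links: CorrespondenceSet | dict[str, str],
) -> StoichiometricMatrix:
    """Embed every reaction of both databases as a signed sparse column."""
    if isinstance(compound_links, CorrespondenceSet):
        a_to_b = compound_links.a_to_b("compound")
    else:
        a_to_b = dict(compound_links)
    for a_cid, b_cid in a_to_b.items():
        if a_cid not in db_a.compounds:
            raise KeyError(f"link references unknown DB-A compound {a_cid}")
        if b_cid not in db_b.compounds:
            raise KeyError(f"link references unknown DB-B compound {b_cid}")
    b_to_a = {b: a for a, b in a_to_b.items()}

    m = StoichiometricMatrix()

    def row_key(db_tag: str, cid: str) -> tuple[str, str]:
        if db_tag == "A" and cid in a_to_b:
            return ("PAIR", f"{cid}={a_to_b[cid]}")
        if db_tag == "B" and cid in b_to_a:
            return ("PAIR", f"{b_to_a[cid]}={cid}")
        return (db_tag, cid)

    for db_tag, db in (("A", db_a), ("B", db_b)):
        for rid in sorted(db.reactions):
            rxn = db.reactions[rid]
            col: dict[int, int] = {}
            for p in rxn.participants:
                r = m._row(row_key(db_tag, p.compound_id))
                sign = -1 if p.side is Side.LEFT else 1
                col[r] = col.get(r, 0) + sign * p.coefficient
            m.columns[(db_tag, rid)] = {r: v for r, v in col.items() if v}
    return m


def cosine_similarity(u: dict[int, int], v: dict[int, int]) -> float:
    """dot(u, v) / (‖u‖·‖v‖) over sparse signed vectors."""
    if not u or not v:
        raise ValueError("cosine undefined for a zero vector")
    if len(u) > len(v):
        u, v = v, u
    dot = sum(val * v.get(r, 0) for r, val in u.items())
    nu = math.sqrt(sum(x * x for x in u.values()))
    nv = math.sqrt(sum(x * x for x in v.values()))
    return dot / (nu * nv)


def uniprot_feature(ra: ReactionRecord, rb: ReactionRecord) -> bool:
    return bool(set(ra.uniprot_accessions) & set(rb.uniprot_accessions))


def ec_feature(ra: ReactionRecord, rb: ReactionRecord) -> bool:
    """Exact full-string EC equality; partial numbers ("1.1.1.-") only match
    identical partial strings."""
    return bool(set(ra.ec_numbers) & set(rb.ec_numbers))


def activity_name_feature(ra: ReactionRecord, rb: ReactionRecord) -> bool:
    ka = {canonicalize_name(n) for n in ra.activity_names} - {""}
    kb = {canonicalize_name(n) for n in rb.activity_names} - {""}
    return bool(ka & kb)


def _features(
    ra: ReactionRecord, rb: ReactionRecord, cfg: ReactionMatchConfig
) -> frozenset[str]:
    feats = set()
    if UNIPROT in cfg.features_enabled and uniprot_feature(ra, rb):
        feats.add(UNIPROT)
    if EC in cfg.features_enabled and ec_feature(ra, rb):
        feats.add(EC)
    if ACTIVITY_NAME in cfg.features_enabled and activity_name_feature(ra, rb):
        feats.add(ACTIVITY_NAME)
    return frozenset(feats)


def infer_reaction_matches(
    db_a: PathwayDB,
    db_b: PathwayDB,
    compound_links: CorrespondenceSet | dict[str, str],
    existing: CorrespondenceSet | None = None,
    cfg: ReactionMatchConfig | None = None,
) -> tuple[list[ReactionMatch], list[ReactionContradiction]]:
    """Main rule (|cos| gate + features + contradiction filter) then the
    one-to-one EC fallback over still-unmatched reactions."""
    cfg = cfg or ReactionMatchConfig()
    existing = existing or CorrespondenceSet()
    matrix = build_stoich_matrix(db_a, db_b, compound_links)

    accepted: dict[str, str] = {}
    accepted_rev: dict[str, str] = {}
    matches: list[ReactionMatch] = []
    for link in existing.of_type("reaction"):
        if link.a_id in accepted or link.b_id in accepted_rev:
            continue
        accepted[link.a_id] = link.b_id
        accepted_rev[link.b_id] = link.a_id
        cos = None
        ca = matrix.columns.get(("A", link.a_id))
        cb = matrix.columns.get(("B", link.b_id))
        if ca and cb:
            cos = cosine_similarity(ca, cb)
        matches.append(
            ReactionMatch(link.a_id, link.b_id, cos, link.features, False, link.source)
        )

    # row -> B columns touching it; only pairs sharing a row can have
    # non-zero dot product
    b_cols_by_row: dict[int, list[tuple[str, dict[int, int]]]] = {}
    for (tag, rid), col in matrix.columns.items():
        if tag != "B":
            continue
        for r in col:
            b_cols_by_row.setdefault(r, []).append((rid, col))

    proposals: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}
    for a_rid in sorted(db_a.reactions):
        if a_rid in accepted:
            continue
        col_a = matrix.columns[("A", a_rid)]
        if not col_a:
            continue
        candidates: set[str] = set()
        for r in col_a:
            candidates.update(rid for rid, _ in b_cols_by_row.get(r, ()))
        ra = db_a.reactions[a_rid]
        for b_rid in sorted(candidates):
            if b_rid in accepted_rev:
                continue
            col_b = matrix.columns[("B", b_rid)]
            if not col_b:
                continue
            cos = cosine_similarity(col_a, col_b)
            if abs(cos) <= cfg.cosine_threshold:
                continue
            feats = _features(ra, db_b.reactions[b_rid], cfg)
            if not feats:
                continue
            proposals[(a_rid, b_rid)] = (cos, feats)

    by_a: dict[str, set[str]] = {}
    by_b: dict[str, set[str]] = {}
    for a, b in proposals:
        by_a.setdefault(a, set()).add(b)
        by_b.setdefault(b, set()).add(a)
    contradictions: list[ReactionContradiction] = []
    voided: set[tuple[str, str]] = set()
    for a, bs in sorted(by_a.items()):
        if len(bs) > 1:
            contradictions.append(ReactionContradiction(a, "A", tuple(sorted(bs))))
            voided.update((a, b) for b in bs)
    for b, as_ in sorted(by_b.items()):
        if len(as_) > 1:
            contradictions.append(ReactionContradiction(b, "B", tuple(sorted(as_))))
            voided.update((a, b) for a in as_)

    for a, b in sorted(set(proposals) - voided):
        cos, feats = proposals[(a, b)]
        accepted[a] = b
        accepted_rev[b] = a
        matches.append(ReactionMatch(a, b, cos, feats))

    if cfg.ec_fallback:
        ec_to_a: dict[str, list[str]] = {}
        ec_to_b: dict[str, list[str]] = {}
        for rid in sorted(db_a.reactions):
            if rid in accepted:
                continue
            for ec in db_a.reactions[rid].ec_numbers:
                ec_to_a.setdefault(ec, []).append(rid)
        for rid in sorted(db_b.reactions):
            if rid in accepted_rev:
                continue
            for ec in db_b.reactions[rid].ec_numbers:
                ec_to_b.setdefault(ec, []).append(rid)
        for ec in sorted(set(ec_to_a) & set(ec_to_b)):
            a_list = [r for r in ec_to_a[ec] if r not in accepted]
            b_list = [r for r in ec_to_b[ec] if r not in accepted_rev]
            if len(a_list) != 1 or len(b_list) != 1:
                continue
            a, b = a_list[0], b_list[0]
            if (a, b) in voided:
                continue  # the fallback never resurrects a voided pair
            cos = None
            col_a = matrix.columns.get(("A", a))
            col_b = matrix.columns.get(("B", b))
            if col_a and col_b:
                cos = cosine_similarity(col_a, col_b)
            accepted[a] = b
            accepted_rev[b] = a
            matches.append(
                ReactionMatch(a, b, cos, frozenset({EC}), via_ec_fallback=True)
            )

    return matches, contradictions


def matches_to_correspondences(
    matches: list[ReactionMatch],
) -> CorrespondenceSet:
    cs = CorrespondenceSet()
    for m in matches:
        cs.add(Link("reaction", m.a_id, m.b_id, m.source, m.features))
    return cs


def _signature(rxn: ReactionRecord) -> tuple[tuple, tuple]:
    l = tuple(sorted(rxn.side_counter(Side.LEFT).items()))
    r = tuple(sorted(rxn.side_counter(Side.RIGHT).items()))
    return min((l, r), (r, l))


def detect_duplicate_reactions(db: PathwayDB) -> list[list[str]]:
    """Clusters of reactions equal up to side reversal (coefficients count)."""
    buckets: dict[tuple, list[str]] = {}
    for rid in sorted(db.reactions):
        buckets.setdefault(_signature(db.reactions[rid]), []).append(rid)
    return [sorted(v) for _, v in sorted(buckets.items()) if len(v) >= 2]


def duplicate_reaction_count(db: PathwayDB) -> int:
    return sum(len(c) - 1 for c in detect_duplicate_reactions(db))
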