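"""Rule-based compound correspondence inference between two databases.

A candidate pair (one compound from each database) is accepted when three
conditions hold simultaneously:

1. at least one *feature* fires from the enabled set —

   - ``FINGERPRINT_STRUCT``: fingerprint Tanimoto similarity strictly above
     the threshold (default 0.75) *and* equal protonation-invariant structure
     keys, so protonation-state differences do not block a match;
   - ``EXACT_STEREO``: byte-identical full structure strings (InChI-style,
     stereo and proton layers included);
   - ``ALL_BUT_ONE``: the pair is the single unmatched substrate pair of an
     already-linked reaction pair;

2. the canonicalized names match exactly (case and punctuation removed; any
   name — common name or synonym — may supply the key); and

3. the pair participates in no contradiction: if any compound acquires two
   or more distinct proposed partners, all implicated pairs are discarded
   and reported.

Curated or imported links supplied in ``existing`` are kept verbatim and
never overridden; inference never relinks an already-linked compound.
``ALL_BUT_ONE`` candidates are generated from reaction links (if present in
``existing``) and iterated to a fixpoint, because each newly inferred
compound link can complete the substrate matching of another reaction pair.

Duplicate detection within one database clusters records with identical
non-empty structure strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .correspondence import CorrespondenceSet, Link
from .db_model import CompoundRecord, PathwayDB

FINGERPRINT_STRUCT = "FINGERPRINT_STRUCT"
EXACT_STEREO = "EXACT_STEREO"
ALL_BUT_ONE = "ALL_BUT_ONE"
ALL_FEATURES = frozenset({FINGERPRINT_STRUCT, EXACT_STEREO, ALL_BUT_ONE})

_NON_ALNUM = re.compile(r"[^a-z0-9]")


@dataclass
class CompoundMatchConfig:
    tanimoto_threshold: float = 0.75  # strict >
    require_name_match: bool = True
    features_enabled: frozenset[str] = ALL_FEATURES

    def __post_init__(self):
        if not (0.0 <= self.tanimoto_threshold <= 1.0):
            raise ValueError("tanimoto_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundMatch:
    a_id: str
    b_id: str
    features: frozenset[str]
    source: str = "inferred"


@dataclass(frozen=True)
class AllButOneCandidate:
    reaction_pair: tuple[str, str]
    c_m: str  # the unmatched compound of the DB-A reaction
    c_k: str  # the unmatched compound of the DB-B reaction


@dataclass
class Contradiction:
    """A compound proposed with two or more distinct partners."""

    compound_id: str
    db: str  # "A" or "B"
    partners: tuple[str, ...]


def canonicalize_name(name: str) -> str:
    """Lowercase and strip every character outside [a-z0-9]."""
    return _NON_ALNUM.sub("", name.lower())


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|a ∩ b| / |a ∪ b| over fingerprint bit sets."""
    if not a and not b:
        raise ValueError("Tanimoto undefined for two empty bit sets")
    union = len(a | b)
    return len(a & b) / union


def fingerprint_structure_feature(
    ca: CompoundRecord, cb: CompoundRecord, cfg: CompoundMatchConfig
) -> bool:
    """Fingerprint similarity gated by the protonation-tolerant structure key."""
    if (
        ca.fingerprint is None
        or cb.fingerprint is None
        or ca.protonation_invariant_key is None
        or cb.protonation_invariant_key is None
    ):
        return False
    if not ca.fingerprint and not cb.fingerprint:
        return False
    if ca.protonation_invariant_key != cb.protonation_invariant_key:
        return False
    return tanimoto(ca.fingerprint, cb.fingerprint) > cfg.tanimoto_threshold


def exact_stereo_feature(ca: CompoundRecord, cb: CompoundRecord) -> bool:
    """Byte-identical full structure strings (stereo + proton layers)."""
    return ca.inchi is not None and cb.inchi is not None and ca.inchi == cb.inchi


def _name_keys(rec: CompoundRecord) -> set[str]:
    return {k for k in (canonicalize_name(n) for n in rec.names()) if k}


def _names_match(ca: CompoundRecord, cb: CompoundRecord) -> bool:
    return bool(_name_keys(ca) & _name_keys(cb))


def all_but_one_candidates(
    reaction_links: set[tuple[str, str]],
    a_to_b: dict[str, str],
    b_to_a: dict[str, str],
    db_a: PathwayDB,
    db_b: PathwayDB,
) -> list[AllButOneCandidate]:
    """Single-residual substrate pairs of linked reaction pairs.

    For a linked reaction pair whose substrate sets are fully matched except
    exactly one compound on each side, and where neither residual compound is
    linked to anything, the residual pair is a candidate.
    """
    out: list[AllButOneCandidate] = []
    for a_rid, b_rid in sorted(reaction_links):
        ra = db_a.reactions.get(a_rid)
        rb = db_b.reactions.get(b_rid)
        if ra is None or rb is None:
            continue
        a_subs = sorted(ra.compound_ids())
        b_subs = set(rb.compound_ids())
        unmatched_a = [c for c in a_subs if a_to_b.get(c) not in b_subs]
        matched_b = {a_to_b[c] for c in a_subs if a_to_b.get(c) in b_subs}
        unmatched_b = sorted(b_subs - matched_b)
        if len(unmatched_a) == 1 and len(unmatched_b) == 1:
            c_m, c_k = unmatched_a[0], unmatched_b[0]
            if c_m not in a_to_b and c_k not in b_to_a:
                out.append(AllButOneCandidate((a_rid, b_rid), c_m, c_k))
    return out


def _resolve_contradictions(
    proposals: set[tuple[str, str]],
) -> tuple[set[tuple[str, str]], list[Contradiction]]:
    """Drop every pair implicated in a multi-partner proposal."""
    by_a: dict[str, set[str]] = {}
    by_b: dict[str, set[str]] = {}
    for a, b in proposals:
        by_a.setdefault(a, set()).add(b)
        by_b.setdefault(b, set()).add(a)
    contradictions: list[Contradiction] = []
    bad: set[tuple[str, str]] = set()
    for a, bs in sorted(by_a.items()):
        if len(bs) > 1:
            contradictions.append(Contradiction(a, "A", tuple(sorted(bs))))
            bad.update((a, b) for b in bs)
    for b, as_ in sorted(by_b.items()):
        if len(as_) > 1:
            contradictions.append(Contradiction(b, "B", tuple(sorted(as_))))
            bad.update((a, b) for a in as_)
    return proposals - bad, contradictions


def infer_compound_matches(
    db_a: PathwayDB,
    db_b: PathwayDB,
    existing: CorrespondenceSet | None = None,
    cfg: CompoundMatchConfig | None = None,
) -> tuple[list[CompoundMatch], list[Contradiction]]:
    """Run the full rule system; returns accepted matches and contradictions.

    The returned matches include the ``existing`` compound links (with their
    original source) followed by inferred ones; the combined set is
    one-to-one.
    """
    cfg = cfg or CompoundMatchConfig()
    existing = existing or CorrespondenceSet()

    accepted: dict[str, str] = {}  # a -> b
    accepted_rev: dict[str, str] = {}
    matches: list[CompoundMatch] = []
    for link in existing.of_type("compound"):
        if link.a_id in accepted or link.b_id in accepted_rev:
            continue
        accepted[link.a_id] = link.b_id
        accepted_rev[link.b_id] = link.a_id
        matches.append(
            CompoundMatch(link.a_id, link.b_id, link.features, link.source)
        )

    # candidate generation: name-key buckets (or structure-key buckets when
    # the name gate is disabled)
    def candidate_pairs() -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        if cfg.require_name_match:
            index: dict[str, list[str]] = {}
            for bid in sorted(db_b.compounds):
                for key in _name_keys(db_b.compounds[bid]):
                    index.setdefault(key, []).append(bid)
            for aid in sorted(db_a.compounds):
                for key in _name_keys(db_a.compounds[aid]):
                    for bid in index.get(key, ()):
                        pairs.add((aid, bid))
        else:
            for keyattr in ("protonation_invariant_key", "inchi"):
                index = {}
                for bid in sorted(db_b.compounds):
                    v = getattr(db_b.compounds[bid], keyattr)
                    if v:
                        index.setdefault(v, []).append(bid)
                for aid in sorted(db_a.compounds):
                    v = getattr(db_a.compounds[aid], keyattr)
                    for bid in index.get(v, ()):
                        pairs.add((aid, bid))
        return pairs

    proposals: dict[tuple[str, str], frozenset[str]] = {}
    for aid, bid in sorted(candidate_pairs()):
        if aid in accepted or bid in accepted_rev:
            continue  # never relink an already-linked compound
        ca, cb = db_a.compounds[aid], db_b.compounds[bid]
        feats = set()
        if FINGERPRINT_STRUCT in cfg.features_enabled and (
            fingerprint_structure_feature(ca, cb, cfg)
        ):
            feats.add(FINGERPRINT_STRUCT)
        if EXACT_STEREO in cfg.features_enabled and exact_stereo_feature(ca, cb):
            feats.add(EXACT_STEREO)
        if not feats:
            continue
        if cfg.require_name_match and not _names_match(ca, cb):
            continue
        proposals[(aid, bid)] = frozenset(feats)

    kept, contradictions = _resolve_contradictions(set(proposals))
    for a, b in sorted(kept):
        accepted[a] = b
        accepted_rev[b] = a
        matches.append(CompoundMatch(a, b, proposals[(a, b)]))

    # all-but-one inference, iterated to fixpoint over the reaction links
    reaction_links = existing.pairs("reaction")
    if ALL_BUT_ONE in cfg.features_enabled and reaction_links:
        while True:
            cands = all_but_one_candidates(
                reaction_links, accepted, accepted_rev, db_a, db_b
            )
            new: set[tuple[str, str]] = set()
            for cand in cands:
                ca = db_a.compounds.get(cand.c_m)
                cb = db_b.compounds.get(cand.c_k)
                if ca is None or cb is None:
                    continue
                if cfg.require_name_match and not _names_match(ca, cb):
                    continue
                new.add((cand.c_m, cand.c_k))
            new_kept, new_contra = _resolve_contradictions(new)
            contradictions.extend(new_contra)
            progressed = False
            for a, b in sorted(new_kept):
                if a in accepted or b in accepted_rev:
                    continue
                accepted[a] = b
                accepted_rev[b] = a
                matches.append(CompoundMatch(a, b, frozenset({ALL_BUT_ONE})))
                progressed = True
            if not progressed:
                break

    return matches, contradictions


def matches_to_correspondences(
    matches: list[CompoundMatch],
) -> CorrespondenceSet:
    cs = CorrespondenceSet()
    for m in matches:
        cs.add(Link("compound", m.a_id, m.b_id, m.source, m.features))
    return cs


def detect_duplicate_compounds(db: PathwayDB) -> list[list[str]]:
    """Clusters (size >= 2) of compounds with identical non-empty structure
    strings; records lacking a structure never cluster."""
    buckets: dict[str, list[str]] = {}
    for cid in sorted(db.compounds):
        inchi = db.compounds[cid].inchi
        if inchi:
            buckets.setdefault(inchi, []).append(cid)
    return [sorted(v) for _, v in sorted(buckets.items()) if len(v) >= 2]


def duplicate_compound_count(db: PathwayDB) -> int:
    """Sum of (cluster size - 1): the number of redundant records."""
    return sum(len(c) - 1 for c in detect_duplicate_compounds(db))
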