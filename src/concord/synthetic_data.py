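"""Synthetic twin pathway databases with known ground truth.

The generator first builds a ground-truth *universe*: a shared pool of
compounds with pseudo-chemical names, formulas, layered structure keys and
bit-set fingerprints, plus reactions that are mass-balanced **by
construction** (product formulas are obtained by re-partitioning the summed
atom bag of the reactants, or by composing previously built balanced
reactions), organized into base/super pathways over a class ontology with
taxonomic ranges.

:func:`derive_views` then projects the universe into two noisy database views
("DB-A" and "DB-B") with controlled overlap and independent per-record noise
processes emulating the divergences seen between real curated pathway
resources: name case/punctuation variation, protonation-state divergence
(+-1 H, proton layer of the structure identifiers altered, the
protonation-invariant key untouched), missing stereo descriptors, fingerprint
bit noise, duplicate records, injected mass imbalance, and partially shared
EC/UniProt/activity-name annotations.  Every true correspondence and every
injection is recorded in a :class:`GroundTruth`, so downstream matching and
auditing stages can be evaluated exactly.

Everything is driven by a single :class:`numpy.random.Generator` seeded from
the config: identical config and seed give byte-identical serialized output.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .db_model import (
    CompoundRecord,
    Direction,
    ElementBag,
    PathwayClassNode,
    PathwayDB,
    PathwayKind,
    PathwayRecord,
    ReactionParticipant,
    ReactionRecord,
    Side,
    TaxonNode,
    format_formula,
    parse_formula,
)


class GeneratorError(Exception):
    pass


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic universe and of the two derived views.

    The defaults define the study conditions under which the matching rule
    system is evaluated: ~500 compounds / ~300 reactions, 70% compound and
    50% reaction sharing, 10% name mangling, 10% protonation divergence, 10%
    stereo loss, 2 fingerprint noise bits, 2% duplicate and 5% imbalance
    injection.  Pathway size means follow the reactions-per-pathway figures
    of curated resources (4.37 for DB-A base pathways, 6.22 for DB-B
    modules).
    """

    seed: int = 0
    n_compounds: int = 500
    n_reactions: int = 300
    shared_compound_fraction: float = 0.7
    shared_reaction_fraction: float = 0.5
    name_mangle_prob: float = 0.1
    synonym_count_range: tuple[int, int] = (1, 3)
    protonation_variant_prob: float = 0.1
    stereo_loss_prob: float = 0.1
    duplicate_compound_rate: float = 0.02
    duplicate_reaction_rate: float = 0.02
    imbalance_rate: float = 0.05
    ec_annotation_prob: float = 0.8
    ec_collision_rate: float = 0.05
    uniprot_share_prob: float = 0.5
    activity_name_share_prob: float = 0.6
    fingerprint_bits: int = 256
    fingerprint_noise_bits: int = 2
    base_pathway_size_mean: float = 4.37
    module_pathway_size_mean: float = 6.22
    n_base_pathways: int = 40
    n_modules: int = 15
    n_superpathways: int = 6
    n_maps: int = 5
    n_classes: int = 12
    n_taxa: int = 15
    class_compound_fraction: float = 0.02
    generic_reaction_fraction: float = 0.02

    def validate(self) -> None:
        props = [
            self.shared_compound_fraction,
            self.shared_reaction_fraction,
            self.name_mangle_prob,
            self.protonation_variant_prob,
            self.stereo_loss_prob,
            self.duplicate_compound_rate,
            self.duplicate_reaction_rate,
            self.imbalance_rate,
            self.ec_annotation_prob,
            self.ec_collision_rate,
            self.uniprot_share_prob,
            self.activity_name_share_prob,
            self.class_compound_fraction,
            self.generic_reaction_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise GeneratorError("all proportions must lie in [0, 1]")
        if self.n_reactions > 0 and self.n_compounds < 2:
            raise GeneratorError("need at least 2 compounds to build reactions")
        if min(
            self.n_compounds,
            self.n_reactions,
            self.n_base_pathways,
            self.n_modules,
            self.n_superpathways,
            self.n_maps,
            self.n_classes,
            self.n_taxa,
            self.fingerprint_bits,
            self.fingerprint_noise_bits,
        ) < 0:
            raise GeneratorError("sizes must be non-negative")
        lo, hi = self.synonym_count_range
        if not (0 <= lo <= hi):
            raise GeneratorError("invalid synonym_count_range")


def zero_noise_config(**overrides) -> GeneratorConfig:
    """A config in which the two views differ only by id renaming.

    All per-record noise processes are off and every annotation is shared, so
    rule-based matching must recover the ground truth exactly.
    """
    base = dict(
        shared_compound_fraction=1.0,
        shared_reaction_fraction=1.0,
        name_mangle_prob=0.0,
        protonation_variant_prob=0.0,
        stereo_loss_prob=0.0,
        duplicate_compound_rate=0.0,
        duplicate_reaction_rate=0.0,
        imbalance_rate=0.0,
        ec_annotation_prob=1.0,
        ec_collision_rate=0.0,
        uniprot_share_prob=1.0,
        activity_name_share_prob=1.0,
        fingerprint_noise_bits=0,
        class_compound_fraction=0.0,
        generic_reaction_fraction=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    d = asdict(config)
    d["synonym_count_range"] = list(config.synonym_count_range)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    if "synonym_count_range" in d:
        d["synonym_count_range"] = tuple(d["synonym_count_range"])
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """True pairings and injected defects of a derived view pair."""

    compound_pairs: set[tuple[str, str]] = field(default_factory=set)
    reaction_pairs: set[tuple[str, str]] = field(default_factory=set)
    injected_unbalanced: set[tuple[str, str]] = field(default_factory=set)
    injected_duplicates: set[tuple[str, str, str]] = field(default_factory=set)
    # (db, view entity id, kind) for stereo/protonation injections
    perturbations: set[tuple[str, str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Naming

_SYLLABLES = [
    "gly", "lac", "pyr", "mal", "fum", "cit", "ser", "thre", "val", "leu",
    "meth", "prop", "but", "pent", "hex", "oxo", "hydro", "keto", "amino",
    "phospho", "acet", "succ", "glut", "arab", "xyl", "rib", "gal", "man",
]
_SUFFIXES = ["ate", "ol", "ine", "ose", "ic acid", "amide", "aldehyde", "yl-CoA"]
_PREFIXES = ["D-", "L-", "2-", "3-", "alpha-", "beta-", "cis-", "trans-"]
_ENZYME_SUFFIXES = [
    "synthase", "dehydrogenase", "kinase", "transferase", "ligase",
    "hydrolase", "mutase", "isomerase", "reductase", "oxidase", "lyase",
    "carboxylase",
]
_ROMAN = ["II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _canonical(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


class _NamePool:
    """Unique pseudo-chemical names with unique canonical keys."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used_keys: set[str] = set()

    def fresh(self) -> str:
        for attempt in range(60):
            parts = [
                _SYLLABLES[self.rng.integers(len(_SYLLABLES))]
                for _ in range(int(self.rng.integers(2, 4)))
            ]
            name = "".join(parts) + _SUFFIXES[self.rng.integers(len(_SUFFIXES))]
            if self.rng.random() < 0.3:
                name = _PREFIXES[self.rng.integers(len(_PREFIXES))] + name
            key = _canonical(name)
            if key not in self.used_keys:
                self.used_keys.add(key)
                return name
        name = f"{name}-{len(self.used_keys)}"
        self.used_keys.add(_canonical(name))
        return name

    def synonym_for(self, base: str) -> str | None:
        """A synonym variant of ``base`` whose key collides with no other name."""
        variants = [
            _PREFIXES[self.rng.integers(len(_PREFIXES))] + base,
            base.upper(),
            base.replace("-", " "),
            base + " anion",
            "iso" + base,
        ]
        v = variants[self.rng.integers(len(variants))]
        key = _canonical(v)
        if key in self.used_keys and key != _canonical(base):
            return None
        self.used_keys.add(key)
        return v


def mangle_name(name: str, rng: np.random.Generator) -> str:
    """Case/punctuation variation that canonicalization must undo."""
    ops = int(rng.integers(1, 3))
    out = name
    for _ in range(ops):
        which = int(rng.integers(4))
        if which == 0:
            out = out.upper() if rng.random() < 0.5 else out.lower()
        elif which == 1:
            out = out.replace("-", " ") if "-" in out else out.replace(" ", "-")
        elif which == 2:
            out = out + "."
        else:
            # insert a dot after the first character
            out = out[:1] + "." + out[1:] if len(out) > 1 else out
    return out


# ---------------------------------------------------------------------------
# Structures and fingerprints

_FP_SET_FRACTION = 3 / 16  # 48 set bits in a 256-bit space


def _random_bag(rng: np.random.Generator) -> ElementBag:
    counts = {
        "C": int(rng.integers(1, 13)),
        "H": int(rng.integers(1, 25)),
    }
    if rng.random() < 0.9:
        counts["O"] = int(rng.integers(1, 9))
    if rng.random() < 0.4:
        counts["N"] = int(rng.integers(1, 5))
    if rng.random() < 0.15:
        counts["P"] = int(rng.integers(1, 4))
    if rng.random() < 0.1:
        counts["S"] = int(rng.integers(1, 3))
    return ElementBag.from_mapping(counts)


def _structure_fields(
    skeleton: str, stereo: str | None, h_count: int
) -> tuple[str, str, str]:
    """(inchi, structure_key, protonation_invariant_key) for one compound.

    The identifiers are layered like real structure strings: a connectivity
    skeleton, an optional stereo layer, and a proton layer.  The
    protonation-invariant key drops the proton layer only; losing the stereo
    descriptor changes both keys (an unspecified stereo center is not the
    same structure statement as a specified one).
    """
    stereo_token = stereo if stereo is not None else "?"
    formula_tag = f"h{h_count}"
    inchi = f"InChI=1X/{skeleton}/{formula_tag}"
    if stereo is not None:
        inchi += f"/t{stereo}"
    structure_key = f"{skeleton}|s{stereo_token}|{formula_tag}"
    pik = f"{skeleton}|s{stereo_token}"
    return inchi, structure_key, pik


def fingerprint_from_structure_key(
    structure_key: str, fingerprint_bits: int
) -> frozenset[int]:
    """Deterministic pseudo-fingerprint: a hash of the structure key seeds
    the choice of set bits, so equal structures share fingerprints and
    distinct structures overlap only by chance."""
    digest = hashlib.sha256(structure_key.encode()).digest()
    seed = int.from_bytes(digest[:4], "little") % (2**31)
    rng = np.random.default_rng(seed)
    n_set = max(4, int(fingerprint_bits * _FP_SET_FRACTION))
    n_set = min(n_set, fingerprint_bits)
    bits = rng.choice(fingerprint_bits, size=n_set, replace=False)
    return frozenset(int(b) for b in bits)


# ---------------------------------------------------------------------------
# Universe generation

_VIEW_ATTR = "X-VIEW"  # universe-only bookkeeping attribute


def _reaction_signature(
    left: Counter, right: Counter
) -> tuple[tuple, tuple]:
    l = tuple(sorted(left.items()))
    r = tuple(sorted(right.items()))
    return min((l, r), (r, l))


def _partition_bag(
    bag: ElementBag, k: int, rng: np.random.Generator
) -> list[ElementBag]:
    k = min(k, bag.total_atoms())
    if k <= 1:
        return [bag]
    parts: list[Counter] = [Counter() for _ in range(k)]
    for e, c in bag.counts:
        alloc = rng.multinomial(c, [1.0 / k] * k)
        for i, a in enumerate(alloc):
            if a:
                parts[i][e] += int(a)
    for i in range(k):
        if sum(parts[i].values()) == 0:
            j = max(range(k), key=lambda j: sum(parts[j].values()))
            if sum(parts[j].values()) <= 1:
                continue
            e = max(parts[j], key=lambda e: parts[j][e])
            parts[j][e] -= 1
            if parts[j][e] == 0:
                del parts[j][e]
            parts[i][e] += 1
    return [
        ElementBag.from_mapping(p) for p in parts if sum(p.values()) > 0
    ]


def generate_universe(config: GeneratorConfig) -> tuple[PathwayDB, dict]:
    """Build the ground-truth universe database.

    Returns the universe :class:`PathwayDB` plus a metadata dict (element
    bags per compound and the id pools, reused by :func:`derive_views`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = PathwayDB(name="UNIVERSE")
    names = _NamePool(rng)

    n_class = int(round(config.n_compounds * config.class_compound_fraction))
    n_regular = config.n_compounds - n_class
    compound_ids = [f"U-C{i:05d}" for i in range(config.n_compounds)]
    regular_ids = compound_ids[:n_regular]
    class_ids = compound_ids[n_regular:]

    bags: dict[str, ElementBag] = {}
    stereo: dict[str, str | None] = {}
    for cid in regular_ids:
        name = names.fresh()
        lo, hi = config.synonym_count_range
        n_syn = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        synonyms = []
        for _ in range(n_syn):
            syn = names.synonym_for(name)
            if syn is not None and syn not in synonyms and syn != name:
                synonyms.append(syn)
        universe.compounds[cid] = CompoundRecord(
            id=cid, common_name=name, synonyms=synonyms
        )
        stereo[cid] = (
            f"{int(rng.integers(1, 10**6))}m" if rng.random() < 0.8 else None
        )
    for k, cid in enumerate(class_ids):
        name = names.fresh()
        universe.compounds[cid] = CompoundRecord(
            id=cid,
            common_name=f"a {name} [class]",
            is_class=True,
            attributes={_VIEW_ATTR: ["A" if k % 2 == 0 else "B"]},
        )

    # --- formulas: an initial reactant pool is assigned up front; the rest
    # receive their formulas when first produced by a reaction, which is what
    # makes every reaction balanced by construction.
    n_init = max(2, int(0.4 * n_regular)) if n_regular >= 2 else n_regular
    assigned: list[str] = []
    unassigned: list[str] = list(regular_ids)
    registry: dict[str, str] = {}  # formula string -> compound id

    def assign_formula(cid: str, bag: ElementBag) -> None:
        bags[cid] = bag
        f = format_formula(bag)
        universe.compounds[cid].formula = f
        registry.setdefault(f, cid)
        assigned.append(cid)
        unassigned.remove(cid)

    for cid in regular_ids[:n_init]:
        assign_formula(cid, _random_bag(rng))

    # --- reactions
    signatures: set[tuple] = set()
    reactions: list[tuple[str, Counter, Counter]] = []

    def register_reaction(left: Counter, right: Counter) -> bool:
        sig = _reaction_signature(left, right)
        if sig in signatures or not left or not right:
            return False
        signatures.add(sig)
        rid = f"U-R{len(reactions):05d}"
        reactions.append((rid, left, right))
        return True

    def fresh_reaction() -> bool:
        n_react = int(rng.integers(1, 4))
        pool = assigned
        if len(pool) < n_react:
            return False
        idx = rng.choice(len(pool), size=n_react, replace=False)
        left: Counter = Counter()
        total = ElementBag.from_mapping({})
        for i in idx:
            cid = pool[int(i)]
            coeff = 1 if rng.random() < 0.8 else 2
            left[cid] += coeff
            total = total + bags[cid].scaled(coeff)
        k = 1 if total.total_atoms() < 6 else int(rng.integers(1, 3))
        parts = _partition_bag(total, k, rng)
        right: Counter = Counter()
        for part in parts:
            f = format_formula(part)
            existing = registry.get(f)
            use_existing = (
                existing is not None
                and existing not in left
                and rng.random() < 0.6
            )
            if use_existing:
                right[existing] += 1
            elif unassigned:
                cid = unassigned[0]
                assign_formula(cid, part)
                right[cid] += 1
            elif existing is not None and existing not in left:
                right[existing] += 1
            else:
                return False
        return register_reaction(left, right)

    def composed_reaction() -> bool:
        if len(reactions) < 2:
            return False
        for _ in range(20):
            i, j = rng.choice(len(reactions), size=2, replace=False)
            _, l1, r1 = reactions[int(i)]
            _, l2, r2 = reactions[int(j)]
            left = l1 + (l2 - r1)
            right = r2 + (r1 - l2)
            # cancel species appearing on both sides (balance preserved)
            for cid in set(left) & set(right):
                m = min(left[cid], right[cid])
                left[cid] -= m
                right[cid] -= m
            left = +left
            right = +right
            if left and right and register_reaction(left, right):
                return True
        # fallback: spectator-extended copy of an existing reaction
        for _ in range(20):
            _, l1, r1 = reactions[int(rng.integers(len(reactions)))]
            spect = assigned[int(rng.integers(len(assigned)))]
            left = l1.copy()
            right = r1.copy()
            left[spect] += 1
            right[spect] += 1
            if register_reaction(left, right):
                return True
        return False

    attempts = 0
    while len(reactions) < config.n_reactions and attempts < 50 * max(
        1, config.n_reactions
    ):
        attempts += 1
        if unassigned:
            fresh_reaction()
        else:
            composed_reaction()
    if len(reactions) < config.n_reactions:
        raise GeneratorError(
            f"could only build {len(reactions)} of {config.n_reactions} reactions"
        )

    # leftover compounds get random formulas (orphan metabolites)
    for cid in list(unassigned):
        assign_formula(cid, _random_bag(rng))

    # structure layers + fingerprints now that all formulas are fixed
    for cid in regular_ids:
        rec = universe.compounds[cid]
        skeleton = f"c{cid[3:]}x{int(rng.integers(16**6)):06x}"
        inchi, skey, pik = _structure_fields(
            skeleton, stereo[cid], bags[cid].get("H")
        )
        rec.inchi = inchi
        rec.structure_key = skey
        rec.protonation_invariant_key = pik
        rec.fingerprint = fingerprint_from_structure_key(
            skey, config.fingerprint_bits
        )
        rec.attributes.setdefault("MOLECULAR-WEIGHT", []).append(
            str(bags[cid].total_atoms() * 8)
        )
        rec.attributes.setdefault("CREATION-DATE", []).append("2012-02-17")
        if rng.random() < 0.2:
            rec.attributes.setdefault("GIBBS-0", []).append(
                f"{rng.normal(-50, 30):.1f}"
            )
        if rng.random() < 0.15:
            rec.comment = f"curator note on {rec.common_name}"

    # --- reaction records with annotations
    ec_counter = 0
    uniprot_counter = 0
    used_ecs: list[str] = []
    activity_keys: set[str] = set()
    for rid, left, right in reactions:
        participants = [
            ReactionParticipant(cid, coeff, Side.LEFT)
            for cid, coeff in sorted(left.items())
        ] + [
            ReactionParticipant(cid, coeff, Side.RIGHT)
            for cid, coeff in sorted(right.items())
        ]
        rec = ReactionRecord(
            id=rid,
            participants=participants,
            direction=(
                Direction.REVERSIBLE
                if rng.random() < 0.3
                else Direction.LEFT_TO_RIGHT
            ),
        )
        if rng.random() < config.ec_annotation_prob:
            if used_ecs and rng.random() < config.ec_collision_rate:
                rec.ec_numbers = [used_ecs[int(rng.integers(len(used_ecs)))]]
            else:
                ec = (
                    f"{int(rng.integers(1, 7))}."
                    f"{int(rng.integers(1, 10))}."
                    f"{int(rng.integers(1, 10))}.{ec_counter + 1}"
                )
                ec_counter += 1
                used_ecs.append(ec)
                rec.ec_numbers = [ec]
        n_up = int(rng.integers(1, 3))
        rec.uniprot_accessions = [
            f"P{50000 + uniprot_counter + i:05d}" for i in range(n_up)
        ]
        uniprot_counter += n_up
        first = universe.compounds[sorted(left)[0]].common_name
        act = f"{first} {_ENZYME_SUFFIXES[int(rng.integers(len(_ENZYME_SUFFIXES)))]}"
        while _canonical(act) in activity_keys:
            act = f"{act} {_ROMAN[int(rng.integers(len(_ROMAN)))]}"
        activity_keys.add(_canonical(act))
        rec.activity_names = [act]
        if rng.random() < 0.05:
            rec.spontaneous = True
        rec.attributes.setdefault("CREATION-DATE", []).append("2012-02-17")
        if rng.random() < 0.5:
            rec.attributes.setdefault("ORPHAN?", []).append("F")
        if rng.random() < 0.3:
            rec.comment = f"literature-derived reaction {rid}"
        universe.reactions[rid] = rec

    # a few generic reactions: add a compound-class cofactor on the left;
    # such reactions are view-exclusive (class frames are not shared) and
    # are skipped by atom-balance auditing (no formula on the class)
    n_generic = int(round(config.generic_reaction_fraction * len(reactions)))
    if class_ids and n_generic:
        rids_sorted = sorted(universe.reactions)
        pick = rng.choice(len(rids_sorted), size=min(n_generic, len(rids_sorted)), replace=False)
        for off, i in enumerate(sorted(int(x) for x in pick)):
            rid = rids_sorted[i]
            cls = class_ids[off % len(class_ids)]
            rec = universe.reactions[rid]
            rec.participants = list(rec.participants) + [
                ReactionParticipant(cls, 1, Side.LEFT)
            ]
            rec.attributes.setdefault(_VIEW_ATTR, []).append(
                universe.compounds[cls].attributes[_VIEW_ATTR][0]
            )

    # --- ontology, taxonomy, pathways
    for i in range(config.n_classes):
        cid = f"U-CLS{i:03d}"
        parents = (
            []
            if i == 0
            else [f"U-CLS{int(rng.integers(0, i)):03d}"]
        )
        universe.classes[cid] = PathwayClassNode(
            id=cid, name=f"pathway class {i}", parent_ids=parents
        )
    for i in range(config.n_taxa):
        tid = str(1000 + i)
        parent = None if i == 0 else str(1000 + int(rng.integers(0, i)))
        universe.taxa[tid] = TaxonNode(
            id=tid, name=f"taxon {1000 + i}", parent_id=parent
        )

    consumers: dict[str, list[str]] = {}
    for rid, rec in universe.reactions.items():
        for p in rec.side(Side.LEFT):
            consumers.setdefault(p.compound_id, []).append(rid)
    for cid in consumers:
        consumers[cid].sort()
    all_rids = sorted(universe.reactions)

    def chain(size: int) -> list[str]:
        out = [all_rids[int(rng.integers(len(all_rids)))]]
        while len(out) < size:
            current = universe.reactions[out[-1]]
            nxt: list[str] = []
            for p in current.side(Side.RIGHT):
                nxt.extend(
                    r for r in consumers.get(p.compound_id, []) if r not in out
                )
            if nxt:
                out.append(nxt[int(rng.integers(len(nxt)))])
            else:
                candidates = [r for r in all_rids if r not in out]
                if not candidates:
                    break
                out.append(candidates[int(rng.integers(len(candidates)))])
        return out

    pwy_counter = 0

    def add_pathway(view: str, kind: PathwayKind, **kwargs) -> str:
        nonlocal pwy_counter
        pid = f"U-P{pwy_counter:04d}"
        pwy_counter += 1
        n_tax = int(rng.integers(1, 3))
        tax = sorted(
            {
                str(1000 + int(rng.integers(config.n_taxa)))
                for _ in range(n_tax)
            }
        ) if config.n_taxa else []
        n_cls = int(rng.integers(1, 3))
        cls = sorted(
            {
                f"U-CLS{int(rng.integers(config.n_classes)):03d}"
                for _ in range(n_cls)
            }
        ) if config.n_classes else []
        universe.pathways[pid] = PathwayRecord(
            id=pid,
            kind=kind,
            class_ids=cls,
            taxonomic_range=tax,
            attributes={_VIEW_ATTR: [view]},
            **kwargs,
        )
        return pid

    base_ids = {"A": [], "B": []}
    if universe.reactions:
        for view, count, mean in (
            ("A", config.n_base_pathways, config.base_pathway_size_mean),
            ("B", config.n_modules, config.module_pathway_size_mean),
        ):
            for _ in range(count):
                size = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
                base_ids[view].append(
                    add_pathway(
                        view, PathwayKind.BASE, reaction_ids=chain(size)
                    )
                )
        for view, count, n_sub_hi, n_extra_hi in (
            ("A", config.n_superpathways, 4, 3),
            ("B", config.n_maps, 6, 5),
        ):
            pool = base_ids[view]
            if not pool:
                continue
            for _ in range(count):
                n_sub = int(rng.integers(2, min(n_sub_hi, len(pool)) + 1))
                subs = sorted(
                    pool[int(i)]
                    for i in rng.choice(len(pool), size=n_sub, replace=False)
                )
                n_extra = int(rng.integers(1, n_extra_hi + 1))
                extra = sorted(
                    {
                        all_rids[int(rng.integers(len(all_rids)))]
                        for _ in range(n_extra)
                    }
                )
                add_pathway(
                    view,
                    PathwayKind.SUPER,
                    reaction_ids=extra,
                    subpathway_ids=subs,
                )

    universe.validate()
    metadata = {"bags": bags, "n_regular": n_regular}
    return universe, metadata


# ---------------------------------------------------------------------------
# View derivation


def _view_of_record(rec) -> str | None:
    vals = rec.attributes.get(_VIEW_ATTR)
    return vals[0] if vals else None


def derive_views(
    universe: PathwayDB, config: GeneratorConfig
) -> tuple[PathwayDB, PathwayDB, GroundTruth]:
    """Project the universe into two noisy views with known correspondences."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2654435761])
    truth = GroundTruth()

    uc_ids = sorted(universe.compounds)
    ur_ids = sorted(universe.reactions)
    regular = [c for c in uc_ids if not universe.compounds[c].is_class]
    class_cpds = [c for c in uc_ids if universe.compounds[c].is_class]

    # 1. reaction assignment: shared / A / B ("generic" reactions follow
    # their class compound's view)
    rxn_assign: dict[str, str] = {}
    for rid in ur_ids:
        rec = universe.reactions[rid]
        forced = _view_of_record(rec)
        if forced:
            rxn_assign[rid] = forced
        elif rng.random() < config.shared_reaction_fraction:
            rxn_assign[rid] = "AB"
        else:
            rxn_assign[rid] = "A" if rng.random() < 0.5 else "B"

    used_by = {"A": set(), "B": set()}
    for rid, assign in rxn_assign.items():
        cids = universe.reactions[rid].compound_ids()
        if "A" in assign or assign == "AB":
            used_by["A"].update(cids)
        if "B" in assign or assign == "AB":
            used_by["B"].update(cids)

    forced_shared = {
        c
        for c in regular
        if c in used_by["A"] and c in used_by["B"]
    }
    n_reg = len(regular)
    n_free = n_reg - len(forced_shared)
    target = config.shared_compound_fraction * n_reg
    q = 0.0
    if n_free > 0:
        q = min(1.0, max(0.0, (target - len(forced_shared)) / n_free))

    cpd_assign: dict[str, str] = {}
    for cid in regular:
        if cid in forced_shared or rng.random() < q:
            cpd_assign[cid] = "AB"
        elif cid in used_by["A"]:
            cpd_assign[cid] = "A"
        elif cid in used_by["B"]:
            cpd_assign[cid] = "B"
        else:
            cpd_assign[cid] = "A" if rng.random() < 0.5 else "B"
    for cid in class_cpds:
        cpd_assign[cid] = _view_of_record(universe.compounds[cid]) or "A"

    views = {"A": PathwayDB(name="DB-A"), "B": PathwayDB(name="DB-B")}
    id_map = {"A": {}, "B": {}}  # universe id -> view id

    # 2. compound copies with per-view noise
    for view in ("A", "B"):
        members = [c for c in uc_ids if view in cpd_assign[c] or cpd_assign[c] == "AB"]
        order = rng.permutation(len(members))
        slot_of = {members[int(i)]: k for k, i in enumerate(order)}
        for ucid in members:
            id_map[view][ucid] = f"{view}-C{slot_of[ucid] + 1:05d}"

    def copy_compound(ucid: str, view: str) -> CompoundRecord:
        src = universe.compounds[ucid]
        rec = CompoundRecord(
            id=id_map[view][ucid],
            common_name=src.common_name,
            synonyms=list(src.synonyms),
            formula=src.formula,
            inchi=src.inchi,
            structure_key=src.structure_key,
            protonation_invariant_key=src.protonation_invariant_key,
            fingerprint=src.fingerprint,
            comment=src.comment,
            is_class=src.is_class,
            attributes={
                k: list(v)
                for k, v in src.attributes.items()
                if k != _VIEW_ATTR
            },
        )
        if rng.random() < config.name_mangle_prob and rec.common_name:
            rec.common_name = mangle_name(rec.common_name, rng)
        rec.synonyms = [
            mangle_name(s, rng) if rng.random() < config.name_mangle_prob else s
            for s in rec.synonyms
        ]
        return rec

    for view in ("A", "B"):
        for ucid in uc_ids:
            if ucid not in id_map[view]:
                continue
            views[view].compounds[id_map[view][ucid]] = copy_compound(
                ucid, view
            )

    db_name = {"A": "DB-A", "B": "DB-B"}

    # 3. structure-level perturbations on shared compounds
    def perturb_protonation(rec: CompoundRecord) -> None:
        if rec.formula is None:
            return
        bag = parse_formula(rec.formula).as_dict()
        h = bag.get("H", 0)
        delta = 1 if h == 0 else int(rng.choice([-1, 1]))
        bag["H"] = h + delta
        if bag["H"] == 0:
            del bag["H"]
        rec.formula = format_formula(ElementBag.from_mapping(bag))
        new_h = bag.get("H", 0)
        if rec.structure_key:
            skeleton, stereo_part, _ = rec.structure_key.split("|")
            stereo = stereo_part[1:]
            stereo = None if stereo == "?" else stereo
            inchi, skey, pik = _structure_fields(skeleton, stereo, new_h)
            rec.inchi, rec.structure_key = inchi, skey
            rec.protonation_invariant_key = pik

    def perturb_stereo(rec: CompoundRecord) -> None:
        if not rec.structure_key:
            return
        skeleton, _, h_part = rec.structure_key.split("|")
        inchi, skey, pik = _structure_fields(skeleton, None, int(h_part[1:]))
        rec.inchi, rec.structure_key = inchi, skey
        rec.protonation_invariant_key = pik

    for ucid in regular:
        if cpd_assign[ucid] != "AB":
            continue
        if rng.random() < config.protonation_variant_prob:
            view = "A" if rng.random() < 0.5 else "B"
            vid = id_map[view][ucid]
            perturb_protonation(views[view].compounds[vid])
            truth.perturbations.add((db_name[view], vid, "protonation"))
        if rng.random() < config.stereo_loss_prob:
            view = "A" if rng.random() < 0.5 else "B"
            vid = id_map[view][ucid]
            perturb_stereo(views[view].compounds[vid])
            truth.perturbations.add((db_name[view], vid, "stereo_loss"))

    # fingerprint bit noise, independent per copy
    if config.fingerprint_noise_bits:
        for view in ("A", "B"):
            for vid in sorted(views[view].compounds):
                rec = views[view].compounds[vid]
                if rec.fingerprint is None:
                    continue
                bits = set(rec.fingerprint)
                flips = rng.choice(
                    config.fingerprint_bits,
                    size=config.fingerprint_noise_bits,
                    replace=False,
                )
                for b in flips:
                    b = int(b)
                    bits.symmetric_difference_update({b})
                rec.fingerprint = frozenset(bits)

    # 4. duplicate compound records
    for view in ("A", "B"):
        dup_n = 0
        for vid in sorted(views[view].compounds):
            rec = views[view].compounds[vid]
            if rec.is_class:
                continue
            if rng.random() < config.duplicate_compound_rate:
                dup_n += 1
                dup_id = f"{view}-CDUP{dup_n:04d}"
                dup = replace(
                    rec,
                    id=dup_id,
                    synonyms=list(rec.synonyms),
                    links=dict(rec.links),
                    attributes={k: list(v) for k, v in rec.attributes.items()},
                )
                views[view].compounds[dup_id] = dup
                truth.injected_duplicates.add((db_name[view], vid, dup_id))

    # 5. reaction copies
    uniprot_fresh = 900000
    activity_fresh = 0
    for view in ("A", "B"):
        members = [
            r
            for r in ur_ids
            if rxn_assign[r] == "AB" or rxn_assign[r] == view
        ]
        order = rng.permutation(len(members))
        slot_of = {members[int(i)]: k for k, i in enumerate(order)}
        for urid in members:
            id_map[view][urid] = f"{view}-R{slot_of[urid] + 1:05d}"
        for urid in members:
            src = universe.reactions[urid]
            rec = ReactionRecord(
                id=id_map[view][urid],
                participants=[
                    ReactionParticipant(
                        id_map[view][p.compound_id], p.coefficient, p.side
                    )
                    for p in src.participants
                ],
                ec_numbers=list(src.ec_numbers),
                uniprot_accessions=list(src.uniprot_accessions),
                activity_names=list(src.activity_names),
                direction=src.direction,
                spontaneous=src.spontaneous,
                comment=src.comment,
                attributes={
                    k: list(v)
                    for k, v in src.attributes.items()
                    if k != _VIEW_ATTR
                },
            )
            if view == "B":
                # annotation sharing is probabilistic; unshared annotations
                # are replaced with fresh values
                if rec.uniprot_accessions and not (
                    rng.random() < config.uniprot_share_prob
                ):
                    rec.uniprot_accessions = [
                        f"P{uniprot_fresh + i}"
                        for i in range(len(rec.uniprot_accessions))
                    ]
                    uniprot_fresh += len(rec.uniprot_accessions)
                if rec.activity_names and not (
                    rng.random() < config.activity_name_share_prob
                ):
                    activity_fresh += 1
                    rec.activity_names = [
                        f"uncharacterized enzyme {activity_fresh}"
                    ]
            rec.activity_names = [
                mangle_name(a, rng)
                if rng.random() < config.name_mangle_prob
                else a
                for a in rec.activity_names
            ]
            views[view].reactions[rec.id] = rec

    for urid in ur_ids:
        if rxn_assign[urid] == "AB":
            truth.reaction_pairs.add((id_map["A"][urid], id_map["B"][urid]))
    for ucid in uc_ids:
        if cpd_assign[ucid] == "AB":
            truth.compound_pairs.add((id_map["A"][ucid], id_map["B"][ucid]))

    # 6. duplicate reaction records
    for view in ("A", "B"):
        dup_n = 0
        for vid in sorted(views[view].reactions):
            if rng.random() < config.duplicate_reaction_rate:
                dup_n += 1
                src = views[view].reactions[vid]
                dup_id = f"{view}-RDUP{dup_n:04d}"
                dup = ReactionRecord(
                    id=dup_id,
                    participants=list(src.participants),
                    ec_numbers=list(src.ec_numbers),
                    uniprot_accessions=list(src.uniprot_accessions),
                    activity_names=list(src.activity_names),
                    direction=src.direction,
                    spontaneous=src.spontaneous,
                    attributes={k: list(v) for k, v in src.attributes.items()},
                )
                views[view].reactions[dup_id] = dup
                truth.injected_duplicates.add((db_name[view], vid, dup_id))

    # 7. imbalance injection: bump one product's coefficient so the defect is
    # local to the reaction and detectable without counting hydrogen
    for view in ("A", "B"):
        db = views[view]
        for vid in sorted(db.reactions):
            rec = db.reactions[vid]
            if any(
                db.compounds[p.compound_id].is_class
                or db.compounds[p.compound_id].formula is None
                for p in rec.participants
            ):
                continue
            if rng.random() >= config.imbalance_rate:
                continue
            candidates = [
                i
                for i, p in enumerate(rec.participants)
                if p.side is Side.RIGHT
                and parse_formula(db.compounds[p.compound_id].formula)
                .without("H")
                .total_atoms()
                > 0
            ]
            if not candidates:
                continue
            i = candidates[int(rng.integers(len(candidates)))]
            p = rec.participants[i]
            rec.participants[i] = ReactionParticipant(
                p.compound_id, p.coefficient + 1, p.side
            )
            truth.injected_unbalanced.add((db_name[view], vid))

    # 8. pathways, classes, taxa per view
    for view in ("A", "B"):
        db = views[view]
        cls_map: dict[str, str] = {}
        for k, ucls in enumerate(sorted(universe.classes)):
            vcid = f"{view}-CLS{k:03d}"
            cls_map[ucls] = vcid
            src = universe.classes[ucls]
            db.classes[vcid] = PathwayClassNode(
                id=vcid,
                name=src.name,
                parent_ids=[cls_map.get(p, p) for p in src.parent_ids],
            )
        # parents may appear later in sort order; remap in a second pass
        for node in db.classes.values():
            node.parent_ids = [
                cls_map[p] if p in cls_map else p for p in node.parent_ids
            ]
        for tid in sorted(universe.taxa):
            src = universe.taxa[tid]
            db.taxa[tid] = TaxonNode(
                id=tid, name=src.name, parent_id=src.parent_id
            )

        pwy_map: dict[str, str] = {}
        members = [
            p
            for p in sorted(universe.pathways)
            if _view_of_record(universe.pathways[p]) == view
        ]
        for k, upid in enumerate(members):
            pwy_map[upid] = f"{view}-P{k + 1:04d}"
        dropped: set[str] = set()
        for upid in members:
            src = universe.pathways[upid]
            rids = [
                id_map[view][r]
                for r in src.reaction_ids
                if r in id_map[view]
            ]
            if src.kind is PathwayKind.BASE and not rids:
                dropped.add(upid)
                continue
            db.pathways[pwy_map[upid]] = PathwayRecord(
                id=pwy_map[upid],
                kind=src.kind,
                reaction_ids=rids,
                subpathway_ids=[
                    pwy_map[s] for s in src.subpathway_ids
                ],
                class_ids=[cls_map[c] for c in src.class_ids],
                taxonomic_range=list(src.taxonomic_range),
            )
        for pwy in db.pathways.values():
            pwy.subpathway_ids = [
                s
                for s in pwy.subpathway_ids
                if s in db.pathways
            ]

    views["A"].validate()
    views["B"].validate()
    return views["A"], views["B"], truth


# ---------------------------------------------------------------------------
# Ground-truth serialization

TRUTH_COMPOUNDS_FILE = "truth_compounds.tsv"
TRUTH_REACTIONS_FILE = "truth_reactions.tsv"
TRUTH_INJECTIONS_FILE = "truth_injections.tsv"


class TruthParseError(Exception):
    pass


def write_truth(truth: GroundTruth, directory: str | Path) -> None:
    """Write ground truth as deterministic TSV files in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fname, etype, pairs in (
        (TRUTH_COMPOUNDS_FILE, "compound", truth.compound_pairs),
        (TRUTH_REACTIONS_FILE, "reaction", truth.reaction_pairs),
    ):
        with open(directory / fname, "w", encoding="utf-8") as fh:
            fh.write("entity_type\ta_id\tb_id\n")
            for a, b in sorted(pairs):
                fh.write(f"{etype}\t{a}\t{b}\n")
    with open(directory / TRUTH_INJECTIONS_FILE, "w", encoding="utf-8") as fh:
        fh.write("kind\tdb\tid1\tid2\n")
        rows = [
            ("unbalanced", db, rid, "") for db, rid in truth.injected_unbalanced
        ]
        rows += [
            ("duplicate", db, kept, dup)
            for db, kept, dup in truth.injected_duplicates
        ]
        rows += [
            ("perturbation", db, eid, kind)
            for db, eid, kind in truth.perturbations
        ]
        for row in sorted(rows):
            fh.write("\t".join(row) + "\n")


def read_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    truth = GroundTruth()
    for fname, etype, target in (
        (TRUTH_COMPOUNDS_FILE, "compound", truth.compound_pairs),
        (TRUTH_REACTIONS_FILE, "reaction", truth.reaction_pairs),
    ):
        with open(directory / fname, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if lineno == 1 or not line:
                    continue
                cols = line.split("\t")
                if len(cols) != 3:
                    raise TruthParseError(
                        f"{fname}:{lineno}: expected 3 columns"
                    )
                if cols[0] != etype:
                    raise TruthParseError(
                        f"{fname}:{lineno}: unknown entity_type {cols[0]!r}"
                    )
                target.add((cols[1], cols[2]))
    path = directory / TRUTH_INJECTIONS_FILE
    if path.is_file():
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if lineno == 1 or not line:
                    continue
                cols = line.split("\t")
                if len(cols) != 4:
                    raise TruthParseError(
                        f"{TRUTH_INJECTIONS_FILE}:{lineno}: expected 4 columns"
                    )
                kind, db, id1, id2 = cols
                if kind == "unbalanced":
                    truth.injected_unbalanced.add((db, id1))
                elif kind == "duplicate":
                    truth.injected_duplicates.add((db, id1, id2))
                elif kind == "perturbation":
                    truth.perturbations.add((db, id1, id2))
                else:
                    raise TruthParseError(
                        f"{TRUTH_INJECTIONS_FILE}:{lineno}: unknown kind {kind!r}"
                    )
    return truth


def generate(
    config: GeneratorConfig,
) -> tuple[PathwayDB, PathwayDB, GroundTruth]:
    """Convenience wrapper: universe + views in one call."""
    universe, _ = generate_universe(config)
    return derive_views(universe, config)
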