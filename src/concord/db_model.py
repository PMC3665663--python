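"""Data model for a metabolic pathway database.

A :class:`PathwayDB` holds five keyed collections — compounds, reactions,
pathways, pathway classes, and taxa — mirroring the three-tier structure of
curated pathway resources (metabolites at the bottom, reactions built on
metabolites, pathways built on reactions) plus the ontologies used to organize
pathways by class and by taxonomic range.

Databases are serialized as a directory of attribute-value flat files
(``compounds.dat``, ``reactions.dat``, ``pathways.dat``, ``classes.dat``,
``taxonomy.dat``) in a BioCyc-style dialect: one ``ATTRIBUTE - VALUE`` line per
fact, records terminated by ``//``, ``#`` comment lines, UTF-8.  The format is
deliberately human-diffable; :func:`write_pathway_db` emits records and
attributes in sorted order so two writes of the same database are
byte-identical.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class PathwayDBError(Exception):
    """Base class for database model errors."""


class FormulaError(PathwayDBError):
    """Raised for malformed molecular formulas; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class LoadError(PathwayDBError):
    """Raised when a database directory cannot be read."""


class FlatFileParseError(PathwayDBError):
    """Malformed flat-file line; names the file and line number."""

    def __init__(self, filename: str, lineno: int, message: str):
        super().__init__(f"{filename}:{lineno}: {message}")
        self.filename = filename
        self.lineno = lineno


class ValidationError(PathwayDBError):
    """Referential-integrity or invariant violation; carries all messages."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Direction(str, Enum):
    LEFT_TO_RIGHT = "LEFT-TO-RIGHT"
    RIGHT_TO_LEFT = "RIGHT-TO-LEFT"
    REVERSIBLE = "REVERSIBLE"
    UNKNOWN = "UNKNOWN"


class PathwayKind(str, Enum):
    #: an individual metabolic pathway (KEGG analogue: module)
    BASE = "BASE"
    #: a composite aggregating base pathways plus extra reactions (analogue: map)
    SUPER = "SUPER"


# ---------------------------------------------------------------------------
# Element bags and formula parsing


@dataclass(frozen=True)
class ElementBag:
    """Multiset of atoms keyed by IUPAC element symbol.

    Absent elements are equivalent to count zero; equality is element-wise.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "ElementBag":
        items = tuple(sorted((e, int(c)) for e, c in counts.items() if c))
        if any(c < 0 for _, c in items):
            raise ValueError("element counts must be non-negative")
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def get(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def total_atoms(self) -> int:
        return sum(c for _, c in self.counts)

    def scaled(self, k: int) -> "ElementBag":
        return ElementBag.from_mapping({e: c * k for e, c in self.counts})

    def __add__(self, other: "ElementBag") -> "ElementBag":
        merged = Counter(dict(self.counts))
        merged.update(dict(other.counts))
        return ElementBag.from_mapping(merged)

    def delta(self, other: "ElementBag") -> dict[str, int]:
        """Signed per-element difference ``self - other`` (zeros omitted)."""
        d = Counter(dict(self.counts))
        d.subtract(dict(other.counts))
        return {e: c for e, c in sorted(d.items()) if c}

    def without(self, element: str) -> "ElementBag":
        return ElementBag.from_mapping(
            {e: c for e, c in self.counts if e != element}
        )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")
_CHARGE_SUFFIX = re.compile(r"([+-]\d*)+$")


def parse_formula(formula: str) -> ElementBag:
    """Parse a molecular formula into exact atom counts.

    Supports element symbols with optional counts and parenthesized groups
    with multipliers, e.g. ``Ca(OH)2`` -> ``{Ca: 1, O: 2, H: 2}``.  Trailing
    charge tokens (``+``, ``-2`` ...) are stripped: balance auditing here is
    atom-based, not charge-based.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula", 0)
    s = _CHARGE_SUFFIX.sub("", formula.strip())
    if not s:
        raise FormulaError(f"formula {formula!r} has no atoms", 0)
    # stack of partial bags; parentheses push/pop
    stack: list[Counter] = [Counter()]
    pos = 0
    n = len(s)
    while pos < n:
        ch = s[pos]
        if ch == "(":
            stack.append(Counter())
            pos += 1
            continue
        if ch == ")":
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' at position {pos}", pos)
            group = stack.pop()
            pos += 1
            m = re.match(r"\d+", s[pos:])
            mult = int(m.group()) if m else 1
            if m:
                pos += m.end()
            for e, c in group.items():
                stack[-1][e] += c * mult
            continue
        m = re.match(r"[A-Z][a-z]?", s[pos:])
        if not m:
            raise FormulaError(
                f"unknown token {s[pos]!r} at position {pos} in {formula!r}", pos
            )
        element = m.group()
        pos += m.end()
        m = re.match(r"\d+", s[pos:])
        count = int(m.group()) if m else 1
        if m:
            pos += m.end()
        stack[-1][element] += count
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {formula!r}", n)
    return ElementBag.from_mapping(stack[0])


def format_formula(bag: ElementBag) -> str:
    """Render an :class:`ElementBag` in Hill order (C, H, then alphabetical)."""
    d = bag.as_dict()
    parts = []
    for e in ("C", "H"):
        if e in d:
            c = d.pop(e)
            parts.append(e if c == 1 else f"{e}{c}")
    for e in sorted(d):
        c = d[e]
        parts.append(e if c == 1 else f"{e}{c}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Records


@dataclass
class CompoundRecord:
    id: str
    common_name: str = ""
    synonyms: list[str] = field(default_factory=list)
    formula: str | None = None
    inchi: str | None = None
    structure_key: str | None = None
    protonation_invariant_key: str | None = None
    fingerprint: frozenset[int] | None = None
    links: dict[str, str] = field(default_factory=dict)
    comment: str | None = None
    is_class: bool = False
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def names(self) -> list[str]:
        out = [self.common_name] if self.common_name else []
        out.extend(self.synonyms)
        return out


@dataclass(frozen=True)
class ReactionParticipant:
    compound_id: str
    coefficient: int = 1
    side: Side = Side.LEFT

    def __post_init__(self):
        if self.coefficient < 1:
            raise ValueError("coefficient must be >= 1")


@dataclass
class ReactionRecord:
    id: str
    participants: list[ReactionParticipant] = field(default_factory=list)
    ec_numbers: list[str] = field(default_factory=list)
    uniprot_accessions: list[str] = field(default_factory=list)
    activity_names: list[str] = field(default_factory=list)
    direction: Direction = Direction.UNKNOWN
    spontaneous: bool | None = None
    links: dict[str, str] = field(default_factory=dict)
    comment: str | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    is_generic: bool = False  # derived: any participant compound is a class

    def side(self, side: Side) -> list[ReactionParticipant]:
        return [p for p in self.participants if p.side is side]

    def side_counter(self, side: Side) -> Counter:
        c: Counter = Counter()
        for p in self.side(side):
            c[p.compound_id] += p.coefficient
        return c

    def compound_ids(self) -> set[str]:
        return {p.compound_id for p in self.participants}


@dataclass
class PathwayRecord:
    id: str
    kind: PathwayKind = PathwayKind.BASE
    reaction_ids: list[str] = field(default_factory=list)
    subpathway_ids: list[str] = field(default_factory=list)
    class_ids: list[str] = field(default_factory=list)
    taxonomic_range: list[str] = field(default_factory=list)
    links: dict[str, str] = field(default_factory=dict)
    comment: str | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PathwayClassNode:
    id: str
    name: str = ""
    parent_ids: list[str] = field(default_factory=list)


@dataclass
class TaxonNode:
    id: str
    name: str = ""
    parent_id: str | None = None


@dataclass
class PathwayDB:
    name: str = "DB"
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    pathways: dict[str, PathwayRecord] = field(default_factory=dict)
    classes: dict[str, PathwayClassNode] = field(default_factory=dict)
    taxa: dict[str, TaxonNode] = field(default_factory=dict)

    def validate(self) -> None:
        """Check referential integrity and structural invariants.

        Also derives each reaction's ``is_generic`` flag (true iff any
        participant denotes a compound class).  Raises :class:`ValidationError`
        listing every offending id.
        """
        problems: list[str] = []
        for rid, rxn in self.reactions.items():
            seen: dict[tuple[str, Side], int] = {}
            for p in rxn.participants:
                if p.compound_id not in self.compounds:
                    problems.append(
                        f"reaction {rid}: unknown compound {p.compound_id}"
                    )
                key = (p.compound_id, p.side)
                seen[key] = seen.get(key, 0) + 1
            if any(v > 1 for v in seen.values()):
                problems.append(
                    f"reaction {rid}: duplicate participant on one side "
                    "(merge coefficients on load)"
                )
            if not rxn.side(Side.LEFT) or not rxn.side(Side.RIGHT):
                if "DEGENERATE" not in rxn.attributes:
                    problems.append(f"reaction {rid}: empty reaction side")
            rxn.is_generic = any(
                self.compounds[p.compound_id].is_class
                for p in rxn.participants
                if p.compound_id in self.compounds
            )
            # canonical participant order so serialization round-trips
            rxn.participants.sort(key=lambda p: (p.side.value, p.compound_id))
        for pid, pwy in self.pathways.items():
            for rid in pwy.reaction_ids:
                if rid not in self.reactions:
                    problems.append(f"pathway {pid}: unknown reaction {rid}")
            for sid in pwy.subpathway_ids:
                if sid not in self.pathways:
                    problems.append(f"pathway {pid}: unknown subpathway {sid}")
            for cid in pwy.class_ids:
                if cid not in self.classes:
                    problems.append(f"pathway {pid}: unknown class {cid}")
            for tid in pwy.taxonomic_range:
                if tid not in self.taxa:
                    problems.append(f"pathway {pid}: unknown taxon {tid}")
            if pwy.kind is PathwayKind.BASE:
                if pwy.subpathway_ids:
                    problems.append(f"pathway {pid}: BASE pathway has subpathways")
                if not pwy.reaction_ids:
                    problems.append(f"pathway {pid}: BASE pathway has no reactions")
        for cid, node in self.classes.items():
            for parent in node.parent_ids:
                if parent not in self.classes:
                    problems.append(f"class {cid}: unknown parent {parent}")
        if _has_cycle({c: n.parent_ids for c, n in self.classes.items()}):
            problems.append("class ontology contains a cycle")
        for tid, node in self.taxa.items():
            if node.parent_id is not None and node.parent_id not in self.taxa:
                problems.append(f"taxon {tid}: unknown parent {node.parent_id}")
        if _has_cycle(
            {
                t: ([n.parent_id] if n.parent_id else [])
                for t, n in self.taxa.items()
            }
        ):
            problems.append("taxonomy contains a cycle")
        if problems:
            raise ValidationError(problems)


def _has_cycle(parents: Mapping[str, list[str]]) -> bool:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in parents}

    def visit(n: str) -> bool:
        color[n] = GREY
        for p in parents.get(n, []):
            if p not in color:
                continue
            if color[p] == GREY:
                return True
            if color[p] == WHITE and visit(p):
                return True
        color[n] = BLACK
        return False

    return any(color[n] == WHITE and visit(n) for n in list(parents))


# ---------------------------------------------------------------------------
# Derived sets


class SubstrateScope(str, Enum):
    ALL_REACTIONS = "ALL_REACTIONS"
    PATHWAY_REACTIONS = "PATHWAY_REACTIONS"


def transitive_reaction_ids(db: PathwayDB, pathway_id: str) -> set[str]:
    """Reactions of a pathway, transitively through subpathways.

    Super pathways are defined in terms of their component pathways plus some
    directly listed reactions, so their reaction set is the closure over both.
    """
    out: set[str] = set()
    stack = [pathway_id]
    seen: set[str] = set()
    while stack:
        pid = stack.pop()
        if pid in seen or pid not in db.pathways:
            continue
        seen.add(pid)
        pwy = db.pathways[pid]
        out.update(pwy.reaction_ids)
        stack.extend(pwy.subpathway_ids)
    return out


def pathway_reaction_set(
    db: PathwayDB, kind: PathwayKind | None = None
) -> set[str]:
    """Union of (transitive) reaction ids over pathways of the given kind."""
    out: set[str] = set()
    for pid, pwy in db.pathways.items():
        if kind is not None and pwy.kind is not kind:
            continue
        out.update(transitive_reaction_ids(db, pid))
    return out


def substrate_set(
    db: PathwayDB,
    scope: SubstrateScope = SubstrateScope.ALL_REACTIONS,
    pathway_kind: PathwayKind | None = None,
) -> set[str]:
    """Union of participant compound ids over the requested reaction scope."""
    if scope is SubstrateScope.ALL_REACTIONS:
        rids: Iterable[str] = db.reactions
    else:
        rids = pathway_reaction_set(db, pathway_kind)
    out: set[str] = set()
    for rid in rids:
        rxn = db.reactions.get(rid)
        if rxn is not None:
            out.update(rxn.compound_ids())
    return out


# ---------------------------------------------------------------------------
# Flat-file I/O

COMPOUNDS_FILE = "compounds.dat"
REACTIONS_FILE = "reactions.dat"
PATHWAYS_FILE = "pathways.dat"
CLASSES_FILE = "classes.dat"
TAXONOMY_FILE = "taxonomy.dat"

_MANDATORY_FILES = (COMPOUNDS_FILE, REACTIONS_FILE, PATHWAYS_FILE)

_ATTR_LINE = re.compile(r"^([A-Za-z0-9?_-]+) - (.*)$")


def iter_flat_records(path: Path) -> Iterator[list[tuple[str, str]]]:
    """Yield records from an attribute-value flat file.

    Each record is the ordered list of ``(attribute, value)`` pairs between
    ``//`` terminators.  ``#`` lines are comments; blank lines are ignored.
    """
    record: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.strip() == "//":
                if record:
                    yield record
                record = []
                continue
            m = _ATTR_LINE.match(line)
            if not m:
                raise FlatFileParseError(
                    path.name, lineno, f"malformed line {line!r}"
                )
            record.append((m.group(1), m.group(2)))
    if record:
        yield record


def _parse_bool(value: str) -> bool:
    return value.strip().upper() in ("T", "TRUE", "YES", "1")


def _parse_dblink(value: str, filename: str) -> tuple[str, str]:
    if ":" not in value:
        raise LoadError(f"{filename}: malformed DBLINK {value!r}")
    db, foreign = value.split(":", 1)
    return db, foreign


def _pop_unique_id(pairs: list[tuple[str, str]], filename: str) -> str:
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            return value
    raise LoadError(f"{filename}: record without UNIQUE-ID")


def _compound_from_pairs(pairs: list[tuple[str, str]]) -> CompoundRecord:
    rec = CompoundRecord(id=_pop_unique_id(pairs, COMPOUNDS_FILE))
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            continue
        elif attr == "COMMON-NAME":
            rec.common_name = value
        elif attr == "SYNONYMS":
            rec.synonyms.append(value)
        elif attr == "FORMULA":
            rec.formula = value
        elif attr == "INCHI":
            rec.inchi = value
        elif attr == "STRUCTURE-KEY":
            rec.structure_key = value
        elif attr == "PROTONATION-INVARIANT-KEY":
            rec.protonation_invariant_key = value
        elif attr == "FINGERPRINT":
            bits = [int(b) for b in value.split(",") if b.strip()]
            rec.fingerprint = frozenset(bits)
        elif attr == "DBLINK":
            db, foreign = _parse_dblink(value, COMPOUNDS_FILE)
            rec.links[db] = foreign
        elif attr == "COMMENT":
            rec.comment = value
        elif attr == "IS-CLASS?":
            rec.is_class = _parse_bool(value)
        else:
            rec.attributes.setdefault(attr, []).append(value)
    return rec


def _reaction_from_pairs(pairs: list[tuple[str, str]]) -> ReactionRecord:
    rec = ReactionRecord(id=_pop_unique_id(pairs, REACTIONS_FILE))
    # (compound_id, side) -> coefficient; COEFFICIENT lines modify the
    # immediately preceding LEFT/RIGHT participant (default 1)
    participants: list[list] = []  # [compound_id, coefficient, side]
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            continue
        elif attr in ("LEFT", "RIGHT"):
            participants.append([value, 1, Side[attr]])
        elif attr == "COEFFICIENT":
            if not participants:
                raise LoadError(
                    f"{REACTIONS_FILE}: COEFFICIENT before any participant "
                    f"in {rec.id}"
                )
            participants[-1][1] = int(value)
        elif attr == "EC-NUMBER":
            rec.ec_numbers.append(value)
        elif attr == "UNIPROT":
            rec.uniprot_accessions.append(value)
        elif attr == "ACTIVITY-NAME":
            rec.activity_names.append(value)
        elif attr == "DIRECTION":
            rec.direction = Direction(value)
        elif attr == "SPONTANEOUS?":
            rec.spontaneous = _parse_bool(value)
        elif attr == "DBLINK":
            db, foreign = _parse_dblink(value, REACTIONS_FILE)
            rec.links[db] = foreign
        elif attr == "COMMENT":
            rec.comment = value
        else:
            rec.attributes.setdefault(attr, []).append(value)
    # tolerant ingestion: merge duplicate participants on one side
    merged: dict[tuple[str, Side], int] = {}
    order: list[tuple[str, Side]] = []
    for cid, coeff, side in participants:
        key = (cid, side)
        if key not in merged:
            order.append(key)
            merged[key] = 0
        merged[key] += coeff
    rec.participants = [
        ReactionParticipant(cid, merged[(cid, side)], side)
        for cid, side in order
    ]
    return rec


def _pathway_from_pairs(pairs: list[tuple[str, str]]) -> PathwayRecord:
    rec = PathwayRecord(id=_pop_unique_id(pairs, PATHWAYS_FILE))
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            continue
        elif attr == "KIND":
            rec.kind = PathwayKind(value)
        elif attr == "REACTION-LIST":
            rec.reaction_ids.append(value)
        elif attr == "SUBPATHWAY":
            rec.subpathway_ids.append(value)
        elif attr == "IN-CLASS":
            rec.class_ids.append(value)
        elif attr == "TAXONOMIC-RANGE":
            rec.taxonomic_range.append(value)
        elif attr == "DBLINK":
            db, foreign = _parse_dblink(value, PATHWAYS_FILE)
            rec.links[db] = foreign
        elif attr == "COMMENT":
            rec.comment = value
        else:
            rec.attributes.setdefault(attr, []).append(value)
    return rec


def _class_from_pairs(pairs: list[tuple[str, str]]) -> PathwayClassNode:
    rec = PathwayClassNode(id=_pop_unique_id(pairs, CLASSES_FILE))
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            continue
        elif attr == "COMMON-NAME":
            rec.name = value
        elif attr == "PARENT":
            rec.parent_ids.append(value)
    return rec


def _taxon_from_pairs(pairs: list[tuple[str, str]]) -> TaxonNode:
    rec = TaxonNode(id=_pop_unique_id(pairs, TAXONOMY_FILE))
    for attr, value in pairs:
        if attr == "UNIQUE-ID":
            continue
        elif attr == "COMMON-NAME":
            rec.name = value
        elif attr == "PARENT":
            rec.parent_id = value
    return rec


def read_pathway_db(
    directory: str | Path, name: str | None = None, validate: bool = True
) -> PathwayDB:
    """Load a pathway database from its flat-file directory.

    ``compounds.dat``, ``reactions.dat`` and ``pathways.dat`` are mandatory;
    ``classes.dat`` and ``taxonomy.dat`` are optional.  The result is
    validated unless ``validate=False``.
    """
    directory = Path(directory)
    for fname in _MANDATORY_FILES:
        if not (directory / fname).is_file():
            raise LoadError(f"missing mandatory file {fname} in {directory}")
    db = PathwayDB(name=name or directory.name)
    for pairs in iter_flat_records(directory / COMPOUNDS_FILE):
        rec = _compound_from_pairs(pairs)
        db.compounds[rec.id] = rec
    for pairs in iter_flat_records(directory / REACTIONS_FILE):
        rec = _reaction_from_pairs(pairs)
        db.reactions[rec.id] = rec
    for pairs in iter_flat_records(directory / PATHWAYS_FILE):
        rec = _pathway_from_pairs(pairs)
        db.pathways[rec.id] = rec
    if (directory / CLASSES_FILE).is_file():
        for pairs in iter_flat_records(directory / CLASSES_FILE):
            rec = _class_from_pairs(pairs)
            db.classes[rec.id] = rec
    if (directory / TAXONOMY_FILE).is_file():
        for pairs in iter_flat_records(directory / TAXONOMY_FILE):
            rec = _taxon_from_pairs(pairs)
            db.taxa[rec.id] = rec
    if validate:
        db.validate()
    return db


def _compound_pairs(rec: CompoundRecord) -> list[tuple[str, str]]:
    pairs = [("UNIQUE-ID", rec.id)]
    if rec.common_name:
        pairs.append(("COMMON-NAME", rec.common_name))
    pairs.extend(("SYNONYMS", s) for s in rec.synonyms)
    if rec.formula is not None:
        pairs.append(("FORMULA", rec.formula))
    if rec.inchi is not None:
        pairs.append(("INCHI", rec.inchi))
    if rec.structure_key is not None:
        pairs.append(("STRUCTURE-KEY", rec.structure_key))
    if rec.protonation_invariant_key is not None:
        pairs.append(("PROTONATION-INVARIANT-KEY", rec.protonation_invariant_key))
    if rec.fingerprint is not None:
        pairs.append(("FINGERPRINT", ",".join(str(b) for b in sorted(rec.fingerprint))))
    for db, foreign in sorted(rec.links.items()):
        pairs.append(("DBLINK", f"{db}:{foreign}"))
    if rec.comment is not None:
        pairs.append(("COMMENT", rec.comment))
    if rec.is_class:
        pairs.append(("IS-CLASS?", "T"))
    for attr in sorted(rec.attributes):
        pairs.extend((attr, v) for v in rec.attributes[attr])
    return pairs


def _reaction_pairs(rec: ReactionRecord) -> list[tuple[str, str]]:
    pairs = [("UNIQUE-ID", rec.id)]
    for side in (Side.LEFT, Side.RIGHT):
        for p in sorted(rec.side(side), key=lambda p: p.compound_id):
            pairs.append((side.value, p.compound_id))
            if p.coefficient != 1:
                pairs.append(("COEFFICIENT", str(p.coefficient)))
    pairs.extend(("EC-NUMBER", e) for e in rec.ec_numbers)
    pairs.extend(("UNIPROT", u) for u in rec.uniprot_accessions)
    pairs.extend(("ACTIVITY-NAME", a) for a in rec.activity_names)
    if rec.direction is not Direction.UNKNOWN:
        pairs.append(("DIRECTION", rec.direction.value))
    if rec.spontaneous is not None:
        pairs.append(("SPONTANEOUS?", "T" if rec.spontaneous else "F"))
    for db, foreign in sorted(rec.links.items()):
        pairs.append(("DBLINK", f"{db}:{foreign}"))
    if rec.comment is not None:
        pairs.append(("COMMENT", rec.comment))
    for attr in sorted(rec.attributes):
        pairs.extend((attr, v) for v in rec.attributes[attr])
    return pairs


def _pathway_pairs(rec: PathwayRecord) -> list[tuple[str, str]]:
    pairs = [("UNIQUE-ID", rec.id), ("KIND", rec.kind.value)]
    pairs.extend(("REACTION-LIST", r) for r in rec.reaction_ids)
    pairs.extend(("SUBPATHWAY", s) for s in rec.subpathway_ids)
    pairs.extend(("IN-CLASS", c) for c in rec.class_ids)
    pairs.extend(("TAXONOMIC-RANGE", t) for t in rec.taxonomic_range)
    for db, foreign in sorted(rec.links.items()):
        pairs.append(("DBLINK", f"{db}:{foreign}"))
    if rec.comment is not None:
        pairs.append(("COMMENT", rec.comment))
    for attr in sorted(rec.attributes):
        pairs.extend((attr, v) for v in rec.attributes[attr])
    return pairs


def _write_flat_file(
    path: Path, records: Iterable[list[tuple[str, str]]]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pairs in records:
            for attr, value in pairs:
                fh.write(f"{attr} - {value}\n")
            fh.write("//\n")


def write_pathway_db(db: PathwayDB, directory: str | Path) -> None:
    """Emit the flat-file dialect; records sorted by id for determinism."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_flat_file(
        directory / COMPOUNDS_FILE,
        (_compound_pairs(db.compounds[c]) for c in sorted(db.compounds)),
    )
    _write_flat_file(
        directory / REACTIONS_FILE,
        (_reaction_pairs(db.reactions[r]) for r in sorted(db.reactions)),
    )
    _write_flat_file(
        directory / PATHWAYS_FILE,
        (_pathway_pairs(db.pathways[p]) for p in sorted(db.pathways)),
    )
    _write_flat_file(
        directory / CLASSES_FILE,
        (
            [("UNIQUE-ID", c)]
            + ([("COMMON-NAME", db.classes[c].name)] if db.classes[c].name else [])
            + [("PARENT", p) for p in db.classes[c].parent_ids]
            for c in sorted(db.classes)
        ),
    )
    _write_flat_file(
        directory / TAXONOMY_FILE,
        (
            [("UNIQUE-ID", t)]
            + ([("COMMON-NAME", db.taxa[t].name)] if db.taxa[t].name else [])
            + ([("PARENT", db.taxa[t].parent_id)] if db.taxa[t].parent_id else [])
            for t in sorted(db.taxa)
        ),
    )
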