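"""Directed A->B entity correspondences with provenance.

A correspondence links an entity of database A to its counterpart in database
B, tagged with its source (``curated`` and ``imported`` links are trusted and
never overridden by inference; ``inferred`` links come from the rule systems
in :mod:`concord.compound_matching` and :mod:`concord.reaction_matching`) and
with the match features that fired.

Serialized as TSV with columns ``entity_type  a_id  b_id  source  features``
(features comma-separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

VALID_SOURCES = ("curated", "imported", "inferred")
VALID_ENTITY_TYPES = ("compound", "reaction")

_HEADER = "entity_type\ta_id\tb_id\tsource\tfeatures"


class CorrespondenceError(Exception):
    pass


@dataclass(frozen=True)
class Link:
    entity_type: str
    a_id: str
    b_id: str
    source: str = "inferred"
    features: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.entity_type not in VALID_ENTITY_TYPES:
            raise CorrespondenceError(
                f"unknown entity_type {self.entity_type!r}"
            )
        if self.source not in VALID_SOURCES:
            raise CorrespondenceError(f"unknown source {self.source!r}")


@dataclass
class CorrespondenceSet:
    links: list[Link] = field(default_factory=list)

    def add(self, link: Link) -> None:
        self.links.append(link)

    def of_type(self, entity_type: str) -> list[Link]:
        return [l for l in self.links if l.entity_type == entity_type]

    def pairs(self, entity_type: str) -> set[tuple[str, str]]:
        return {(l.a_id, l.b_id) for l in self.of_type(entity_type)}

    def a_to_b(self, entity_type: str) -> dict[str, str]:
        return {l.a_id: l.b_id for l in self.of_type(entity_type)}

    def b_to_a(self, entity_type: str) -> dict[str, str]:
        return {l.b_id: l.a_id for l in self.of_type(entity_type)}

    def is_one_to_one(self, entity_type: str) -> bool:
        links = self.of_type(entity_type)
        return len({l.a_id for l in links}) == len(links) and len(
            {l.b_id for l in links}
        ) == len(links)

    def sorted(self) -> "CorrespondenceSet":
        return CorrespondenceSet(
            sorted(
                self.links,
                key=lambda l: (l.entity_type, l.a_id, l.b_id, l.source),
            )
        )

    def __len__(self) -> int:
        return len(self.links)


def write_correspondences(cs: CorrespondenceSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for l in cs.sorted().links:
            feats = ",".join(sorted(l.features))
            fh.write(f"{l.entity_type}\t{l.a_id}\t{l.b_id}\t{l.source}\t{feats}\n")


def read_correspondences(path: str | Path) -> CorrespondenceSet:
    cs = CorrespondenceSet()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or (lineno == 1 and line == _HEADER):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise CorrespondenceError(
                    f"{path}:{lineno}: expected 5 columns, got {len(cols)}"
                )
            entity_type, a_id, b_id, source, feats = cols
            try:
                cs.add(
                    Link(
                        entity_type,
                        a_id,
                        b_id,
                        source,
                        frozenset(f for f in feats.split(",") if f),
                    )
                )
            except CorrespondenceError as exc:
                raise CorrespondenceError(f"{path}:{lineno}: {exc}") from exc
    return cs
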