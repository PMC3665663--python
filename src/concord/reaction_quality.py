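"""Atom-balance auditing of reactions.

The balance checker sums coefficient-weighted atom counts on each side of a
reaction and compares them element-wise.  Because databases differ in the
protonation conventions of their compounds, hydrogen imbalance is a
potentially less serious defect than imbalance in any other element, so each
report carries two flags: ``balanced_all`` (every element, hydrogen
included) and ``balanced_no_h`` (every element except hydrogen).
Reactions with any participant lacking a parseable formula are *skipped*,
not failed — curated databases legitimately contain structureless compounds
and compound classes.

The "high quality reaction" summary subtracts duplicate and unbalanced
(hydrogen counted) records from the total reaction count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .db_model import (
    ElementBag,
    FormulaError,
    PathwayDB,
    Side,
    parse_formula,
)
from .reaction_matching import duplicate_reaction_count


@dataclass
class BalanceReport:
    reaction_id: str
    balanced_all: bool
    balanced_no_h: bool
    per_element_delta: dict[str, int]  # right minus left; zeros omitted
    skipped: bool = False


def reaction_balance(db: PathwayDB, reaction_id: str) -> BalanceReport:
    """Balance report for one reaction; skipped when a formula is missing."""
    if reaction_id not in db.reactions:
        raise KeyError(f"unknown reaction {reaction_id}")
    rxn = db.reactions[reaction_id]
    sides = {Side.LEFT: ElementBag.from_mapping({}), Side.RIGHT: ElementBag.from_mapping({})}
    for p in rxn.participants:
        cpd = db.compounds.get(p.compound_id)
        formula = cpd.formula if cpd is not None else None
        if formula is None:
            return BalanceReport(reaction_id, False, False, {}, skipped=True)
        try:
            bag = parse_formula(formula)
        except FormulaError:
            return BalanceReport(reaction_id, False, False, {}, skipped=True)
        sides[p.side] = sides[p.side] + bag.scaled(p.coefficient)
    delta = sides[Side.RIGHT].delta(sides[Side.LEFT])
    balanced_all = not delta
    balanced_no_h = not {e: c for e, c in delta.items() if e != "H"}
    return BalanceReport(reaction_id, balanced_all, balanced_no_h, delta)


def balance_reports(db: PathwayDB) -> list[BalanceReport]:
    return [reaction_balance(db, rid) for rid in sorted(db.reactions)]


def unbalanced_counts(db: PathwayDB) -> tuple[int, int, int]:
    """(unbalanced ignoring H, unbalanced counting H, skipped)."""
    no_h = with_h = skipped = 0
    for rep in balance_reports(db):
        if rep.skipped:
            skipped += 1
        else:
            if not rep.balanced_no_h:
                no_h += 1
            if not rep.balanced_all:
                with_h += 1
    return no_h, with_h, skipped


def high_quality_count(
    total: int, duplicates: int, unbalanced_with_h: int
) -> int:
    """Plain subtraction of duplicate and unbalanced records from the total.

    A record that is both duplicate and unbalanced is subtracted twice; the
    summary deliberately mirrors simple per-defect bookkeeping rather than an
    overlap-aware count.
    """
    return total - duplicates - unbalanced_with_h


def high_quality_reaction_count(db: PathwayDB) -> int:
    _, with_h, _ = unbalanced_counts(db)
    return high_quality_count(
        len(db.reactions), duplicate_reaction_count(db), with_h
    )
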