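"""End-to-end correspondence inference between two pathway databases.

The stages feed each other: compound links raise the stoichiometric cosine
of truly corresponding reactions, and accepted reaction links enable
all-but-one compound inference, which in turn can complete further reaction
pairs.  The pipeline therefore runs compound matching, then reaction
matching, then a second compound pass with all-but-one enabled over the
reaction links, and a final reaction pass over the enriched compound links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import compound_matching as cm
from . import reaction_matching as rm
from .correspondence import CorrespondenceSet, Link
from .db_model import PathwayDB


@dataclass
class PipelineResult:
    compound_matches: list[cm.CompoundMatch]
    reaction_matches: list[rm.ReactionMatch]
    compound_contradictions: list = field(default_factory=list)
    reaction_contradictions: list = field(default_factory=list)

    def correspondences(self) -> CorrespondenceSet:
        cs = CorrespondenceSet()
        for m in self.compound_matches:
            cs.add(Link("compound", m.a_id, m.b_id, m.source, m.features))
        for m in self.reaction_matches:
            cs.add(Link("reaction", m.a_id, m.b_id, m.source, m.features))
        return cs

    def compound_pairs(self) -> set[tuple[str, str]]:
        return {(m.a_id, m.b_id) for m in self.compound_matches}

    def reaction_pairs(self) -> set[tuple[str, str]]:
        return {(m.a_id, m.b_id) for m in self.reaction_matches}


def infer_all_correspondences(
    db_a: PathwayDB,
    db_b: PathwayDB,
    existing: CorrespondenceSet | None = None,
    compound_cfg: cm.CompoundMatchConfig | None = None,
    reaction_cfg: rm.ReactionMatchConfig | None = None,
) -> PipelineResult:
    existing = existing or CorrespondenceSet()
    compound_cfg = compound_cfg or cm.CompoundMatchConfig()
    reaction_cfg = reaction_cfg or rm.ReactionMatchConfig()

    cpd_matches, cpd_contra = cm.infer_compound_matches(
        db_a, db_b, existing, compound_cfg
    )
    links = CorrespondenceSet(list(existing.of_type("reaction")))
    for m in cpd_matches:
        links.add(Link("compound", m.a_id, m.b_id, m.source, m.features))

    rxn_matches, rxn_contra = rm.infer_reaction_matches(
        db_a, db_b, links, existing, reaction_cfg
    )

    # second compound pass: the accepted reaction links enable all-but-one
    combined = CorrespondenceSet(list(links.links))
    for m in rxn_matches:
        combined.add(Link("reaction", m.a_id, m.b_id, m.source, m.features))
    cpd_matches2, cpd_contra2 = cm.infer_compound_matches(
        db_a, db_b, combined, compound_cfg
    )

    links2 = CorrespondenceSet()
    for m in cpd_matches2:
        links2.add(Link("compound", m.a_id, m.b_id, m.source, m.features))
    rxn_matches2, rxn_contra2 = rm.infer_reaction_matches(
        db_a, db_b, links2, existing, reaction_cfg
    )

    return PipelineResult(
        compound_matches=cpd_matches2,
        reaction_matches=rxn_matches2,
        compound_contradictions=cpd_contra + cpd_contra2,
        reaction_contradictions=rxn_contra + rxn_contra2,
    )
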