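import pytest

from concord.db_model import (
    CompoundRecord,
    PathwayDB,
    PathwayKind,
    PathwayRecord,
    ReactionParticipant,
    ReactionRecord,
    Side,
)
from concord.pipeline import infer_all_correspondences
from concord.synthetic_data import GeneratorConfig, generate, zero_noise_config


@pytest.fixture(scope="session")
def default_twin():
    """Twin databases under the default (noisy) study conditions."""
    return generate(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def zero_twin():
    """Twin databases differing only by id renaming."""
    return generate(zero_noise_config(seed=202))


@pytest.fixture(scope="session")
def default_pipeline(default_twin):
    db_a, db_b, _ = default_twin
    return infer_all_correspondences(db_a, db_b)


@pytest.fixture
def tiny_db():
    """Hand-built database: glycolysis-flavoured 5-compound, 3-reaction toy.

    R1: glc + atp -> g6p + adp   (in base pathway P1)
    R2: g6p -> f6p               (in base pathway P1)
    R3: f6p -> glc               (outside pathways; super SP adds it)
    """
    db = PathwayDB(name="TINY")
    formulas = {
        "glc": "C6H12O6",
        "atp": "C10H16N5O13P3",
        "g6p": "C6H13O9P",
        "adp": "C10H15N5O10P2",
        "f6p": "C6H13O9P",
    }
    for cid, f in formulas.items():
        db.compounds[cid] = CompoundRecord(id=cid, common_name=cid, formula=f)
    db.reactions["R1"] = ReactionRecord(
        "R1",
        [
            ReactionParticipant("glc", 1, Side.LEFT),
            ReactionParticipant("atp", 1, Side.LEFT),
            ReactionParticipant("g6p", 1, Side.RIGHT),
            ReactionParticipant("adp", 1, Side.RIGHT),
        ],
    )
    db.reactions["R2"] = ReactionRecord(
        "R2",
        [
            ReactionParticipant("g6p", 1, Side.LEFT),
            ReactionParticipant("f6p", 1, Side.RIGHT),
        ],
    )
    db.reactions["R3"] = ReactionRecord(
        "R3",
        [
            ReactionParticipant("f6p", 1, Side.LEFT),
            ReactionParticipant("glc", 1, Side.RIGHT),
        ],
    )
    db.pathways["P1"] = PathwayRecord(
        "P1", PathwayKind.BASE, reaction_ids=["R1", "R2"]
    )
    db.pathways["SP"] = PathwayRecord(
        "SP",
        PathwayKind.SUPER,
        reaction_ids=["R3"],
        subpathway_ids=["P1"],
    )
    db.validate()
    return db
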