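import numpy as np
import pandas as pd
import pytest

from pascloud import (
    ExpressionMatrix,
    GeneRole,
    Group,
    GroupDesign,
    Pathway,
    PathwayDatabase,
    Role,
)


@pytest.fixture
def demo_pathway() -> Pathway:
    """Two activators and one repressor, unit weights."""
    return Pathway(
        pathway_id="P1",
        name="demo",
        members=(
            GeneRole("ACT1", Role.ACTIVATOR, 1.0),
            GeneRole("ACT2", Role.ACTIVATOR, 1.0),
            GeneRole("REP1", Role.REPRESSOR, -1.0),
        ),
    )


@pytest.fixture
def demo_db(demo_pathway) -> PathwayDatabase:
    other = Pathway(
        pathway_id="P2",
        name="other",
        members=(
            GeneRole("ACT3", Role.ACTIVATOR, 1.0),
            GeneRole("REP2", Role.REPRESSOR, -1.0),
        ),
    )
    return PathwayDatabase(pathways=(demo_pathway, other))


@pytest.fixture
def demo_matrix() -> ExpressionMatrix:
    """5 genes x (2 case + 3 control); controls constant at 10 except REP1."""
    genes = ["ACT1", "ACT2", "REP1", "ACT3", "REP2"]
    data = {
        "c1": [40.0, 40.0, 2.0, 10.0, 10.0],
        "c2": [40.0, 40.0, 2.0, 10.0, 10.0],
        "n1": [10.0, 10.0, 8.0, 10.0, 10.0],
        "n2": [10.0, 10.0, 10.0, 10.0, 10.0],
        "n3": [10.0, 10.0, 12.0, 10.0, 10.0],
    }
    return ExpressionMatrix(pd.DataFrame(data, index=genes))


@pytest.fixture
def demo_design() -> GroupDesign:
    return GroupDesign(
        assignment={
            "c1": Group.CASE,
            "c2": Group.CASE,
            "n1": Group.CONTROL,
            "n2": Group.CONTROL,
            "n3": Group.CONTROL,
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
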