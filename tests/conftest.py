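import pandas as pd
import pytest

from ocean.network import Metabolite, Reaction, ReactionNetwork


@pytest.fixture
def chain3() -> ReactionNetwork:
    """A -(E1)-> B -(E2)-> C, one compartment, simple gene rules."""
    return ReactionNetwork.from_lists(
        [
            Metabolite("A_c", "A", "c", "C6H12O6"),
            Metabolite("B_c", "B", "c", "C6H12O6"),
            Metabolite("C_c", "C", "c", "C6H12O6"),
        ],
        [
            Reaction("r1", (("A_c", 1.0),), (("B_c", 1.0),), "forward", "g1"),
            Reaction("r2", (("B_c", 1.0),), (("C_c", 1.0),), "forward", "g2"),
        ],
    )


@pytest.fixture
def cycle2() -> ReactionNetwork:
    """Two-reaction cycle A -(E1)-> B -(E2)-> A."""
    return ReactionNetwork.from_lists(
        [
            Metabolite("A_c", "A", "c", "C6H12O6"),
            Metabolite("B_c", "B", "c", "C6H12O6"),
        ],
        [
            Reaction("r1", (("A_c", 1.0),), (("B_c", 1.0),), "forward", "g1"),
            Reaction("r2", (("B_c", 1.0),), (("A_c", 1.0),), "forward", "g2"),
        ],
    )


@pytest.fixture
def abundance6():
    """Balanced 3v3 two-batch design with 2 QC injections, 4 metabolites."""
    from ocean.stats import AbundanceMatrix

    areas = pd.DataFrame(
        {
            "m1": [100.0, 110, 105, 95, 102, 98, 101, 103],
            "m2": [50.0, 55, 52, 48, 51, 49, 50, 51],
            "m3": [200.0, 210, 205, 195, 202, 198, 201, 202],
            "m4": [20.0, 22, 21, 19, 20, 21, 20, 20],
        },
        index=pd.Index(
            ["c1", "c2", "c3", "t1", "t2", "t3", "q1", "q2"], name="sample"
        ),
    )
    design = pd.DataFrame(
        {
            "group": ["CTRL", "CTRL", "CTRL", "CASE", "CASE", "CASE", "", ""],
            "batch": ["B0", "B1", "B0", "B1", "B0", "B1", "B0", "B1"],
            "is_qc": [False] * 6 + [True, True],
        },
        index=areas.index,
    )
    return AbundanceMatrix(areas, design)
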