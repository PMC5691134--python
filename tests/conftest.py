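import numpy as np
import pytest

import fluxgames as fg


@pytest.fixture(scope="session")
def linear_model():
    """A_ext -(EX)-> A -(R1)-> B -(BIOMASS consumes B)."""
    return fg.MetabolicNetwork(
        metabolites=("A", "B"),
        reactions=("EX_A", "R1", "BIOMASS"),
        stoich={
            ("A", "EX_A"): -1.0,
            ("A", "R1"): -1.0,
            ("B", "R1"): 1.0,
            ("B", "BIOMASS"): -1.0,
        },
        lower_bound={"EX_A": -10.0, "R1": 0.0, "BIOMASS": 0.0},
        upper_bound={"EX_A": 0.0, "R1": 1000.0, "BIOMASS": 1000.0},
        biomass_reaction="BIOMASS",
        exchanges={"A": "EX_A"},
        gene_map={"g1": {"R1"}},
    )


@pytest.fixture(scope="session")
def allocation_model():
    """One unit of carbon yields either one biomass unit or one exported
    amino acid unit; uptake bound 10 (closed-form e_max oracle = 10)."""
    return fg.MetabolicNetwork(
        metabolites=("carb", "prec", "aaA"),
        reactions=("EX_carb", "ANA", "SYN_A", "EX_A", "BIOMASS"),
        stoich={
            ("carb", "EX_carb"): -1.0,
            ("carb", "ANA"): -1.0,
            ("prec", "ANA"): 1.0,
            ("prec", "SYN_A"): -1.0,
            ("aaA", "SYN_A"): 1.0,
            ("aaA", "EX_A"): -1.0,
            ("prec", "BIOMASS"): -1.0,
        },
        lower_bound={r: 0.0 for r in ("ANA", "SYN_A", "EX_A", "BIOMASS")} | {"EX_carb": -10.0},
        upper_bound={r: 1000.0 for r in ("ANA", "SYN_A", "EX_A", "BIOMASS")} | {"EX_carb": 0.0},
        biomass_reaction="BIOMASS",
        exchanges={"carb": "EX_carb", "aaA": "EX_A"},
        gene_map={"synA": {"SYN_A"}},
    )


@pytest.fixture(scope="session")
def sucrose_system():
    return fg.make_sucrose_fixture(atp_cost_x=1.0, public_fraction=0.6)


@pytest.fixture(scope="session")
def amino_system():
    return fg.make_two_amino_acid_fixture(leakiness_A=40.0, leakiness_B=40.0)


@pytest.fixture(scope="session")
def amino_tensor(amino_system):
    return amino_system.build_tensor()


@pytest.fixture
def rng():
    return np.random.default_rng(20170)
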