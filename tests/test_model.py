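"""FBA core: LP correctness, status reporting, IO round trips."""

import json

import numpy as np
import pytest
from scipy.optimize import linprog

import fluxgames as fg
from fluxgames.errors import InputError, ModelValidationError


def dense_lp_biomass(model, extra=None):
    """Independent oracle: dense constraint assembly + generic LP solve."""
    mets, rxns = list(model.metabolites), list(model.reactions)
    A = np.zeros((len(mets), len(rxns)))
    for (m, r), s in model.stoich.items():
        A[mets.index(m), rxns.index(r)] = s
    bounds = [(model.lower_bound[r], model.upper_bound[r]) for r in rxns]
    for r, b in (extra or {}).items():
        bounds[rxns.index(r)] = (b, b) if np.isscalar(b) else b
    c = np.zeros(len(rxns))
    c[rxns.index(model.biomass_reaction)] = -1.0
    res = linprog(c, A_eq=A, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    return (-res.fun) if res.status == 0 else None


def test_linear_pathway_rate_limited_by_uptake(linear_model):
    res = fg.solve_fba(linear_model)
    assert res.optimal
    assert res.biomass_flux == pytest.approx(10.0, abs=1e-9)
    assert fg.check_solution(linear_model, res)


def test_severed_pathway_gives_zero_biomass(linear_model):
    res = fg.solve_fba(linear_model, {"R1": 0.0})
    assert res.optimal
    assert res.biomass_flux == pytest.approx(0.0, abs=1e-9)


def test_unknown_reaction_in_override_raises(linear_model):
    with pytest.raises(InputError):
        fg.solve_fba(linear_model, {"NOPE": 0.0})


def test_missing_exchange_bound_reported_unbounded(linear_model):
    # removing the uptake and internal caps makes the biomass flux unbounded
    res = fg.solve_fba(
        linear_model,
        {"EX_A": (-np.inf, 0.0), "R1": (0.0, np.inf), "BIOMASS": (0.0, np.inf)},
    )
    assert res.status == "unbounded"


def test_contradictory_override_is_infeasible(linear_model):
    res = fg.solve_fba(linear_model, {"BIOMASS": (20.0, 30.0)})
    assert res.status == "infeasible"


@pytest.mark.parametrize("seed", range(8))
def test_random_networks_match_dense_lp_oracle(seed):
    model = fg.make_random_viable_fixture(n_metabolites=8, n_reactions=12, seed=seed)
    res = fg.solve_fba(model)
    assert res.optimal
    assert res.biomass_flux == pytest.approx(dense_lp_biomass(model), abs=1e-6)
    assert fg.check_solution(model, res)


def test_bound_scaling_scales_biomass(linear_model):
    lam = 3.5
    scaled = fg.MetabolicNetwork(
        metabolites=linear_model.metabolites,
        reactions=linear_model.reactions,
        stoich=linear_model.stoich,
        lower_bound={r: lam * b for r, b in linear_model.lower_bound.items()},
        upper_bound={r: lam * b for r, b in linear_model.upper_bound.items()},
        biomass_reaction=linear_model.biomass_reaction,
        exchanges=linear_model.exchanges,
        gene_map=linear_model.gene_map,
    )
    assert fg.solve_fba(scaled).biomass_flux == pytest.approx(
        lam * fg.solve_fba(linear_model).biomass_flux, rel=1e-9
    )


@pytest.mark.parametrize("seed", range(5))
def test_tightening_bounds_never_increases_biomass(seed):
    model = fg.make_random_viable_fixture(seed=seed)
    base = fg.solve_fba(model).biomass_flux
    rng = np.random.default_rng(seed)
    rxn = model.reactions[rng.integers(len(model.reactions))]
    lo, hi = model.lower_bound[rxn], model.upper_bound[rxn]
    tightened = fg.solve_fba(model, {rxn: (lo, lo + 0.5 * (hi - lo))})
    assert tightened.status == "infeasible" or tightened.biomass_flux <= base + 1e-9


# --------------------------------------------------------------------- #
# IO
# --------------------------------------------------------------------- #
def test_json_round_trip(sucrose_system, tmp_path):
    path = tmp_path / "model.json"
    fg.write_model(sucrose_system.model, path)
    again = fg.read_model(path)
    assert again == sucrose_system.model


def test_missing_biomass_key_is_validation_error(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"metabolites": ["A"], "reactions": []}))
    with pytest.raises(ModelValidationError, match="biomass"):
        fg.read_model(path)


def test_invalid_invariants_listed():
    with pytest.raises(ModelValidationError) as err:
        fg.MetabolicNetwork(
            metabolites=("A",),
            reactions=("R",),
            stoich={("A", "R"): 1.0},
            lower_bound={"R": 5.0},
            upper_bound={"R": 1.0},
            biomass_reaction="MISSING",
        )
    msg = str(err.value)
    assert "LB" in msg and "MISSING" in msg


def test_sbml_import_maps_species_reactions_and_objective(tmp_path):
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("mini")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")
    ex = cobra.Reaction("EX_A", lower_bound=-10.0, upper_bound=0.0)
    ex.add_metabolites({a: -1})
    r1 = cobra.Reaction("R1", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({a: -1, b: 1})
    bio = cobra.Reaction("BIO", lower_bound=0.0, upper_bound=1000.0)
    bio.add_metabolites({b: -1})
    cm.add_reactions([ex, r1, bio])
    cm.objective = "BIO"
    path = tmp_path / "mini.xml"
    cobra.io.write_sbml_model(cm, str(path))

    model = fg.read_model(path, format="sbml")
    assert len(model.metabolites) == 2
    assert len(model.reactions) == 3
    assert model.biomass_reaction == "BIO"
    assert model.lower_bound["EX_A"] == -10.0
    assert fg.solve_fba(model).biomass_flux == pytest.approx(10.0, abs=1e-6)
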