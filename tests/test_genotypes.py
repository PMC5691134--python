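"""Genotype constraints: deletions, forced leakage, uptake, max leakiness."""

import pytest

import fluxgames as fg
from fluxgames.errors import InputError
from fluxgames.genotypes import apply_genotype, genotype_fba, max_sustainable_leakiness


def test_empty_genotype_equals_plain_fba(allocation_model):
    g = fg.Genotype(label="WT")
    assert genotype_fba(allocation_model, g).biomass_flux == pytest.approx(
        fg.solve_fba(allocation_model).biomass_flux
    )


def test_deletion_fixes_flux_to_zero(allocation_model):
    g = fg.from_gene_deletions(allocation_model, {"synA"}, label="noA")
    res = genotype_fba(allocation_model, g)
    assert res.optimal
    assert res.fluxes["SYN_A"] == pytest.approx(0.0, abs=1e-9)


def test_forced_leak_is_respected(allocation_model):
    g = fg.Genotype(label="leaker", leaky={"aaA": 3.0})
    res = genotype_fba(allocation_model, g)
    assert res.optimal
    assert res.fluxes["EX_A"] >= 3.0 - 1e-9
    # the leaked carbon is lost to growth
    assert res.biomass_flux == pytest.approx(7.0, abs=1e-6)


def test_uptake_is_permitted_not_forced(amino_system):
    model = amino_system.model
    g = fg.Genotype(label="free", uptakes={"aaA": 5.0})
    overrides = apply_genotype(model, g)
    assert overrides["EX_A"][0] == -5.0
    res = genotype_fba(model, g)
    assert res.optimal  # nothing forces the uptake flux


def test_deleting_biomass_reaction_rejected(allocation_model):
    g = fg.Genotype(label="dead", deleted_reactions={"BIOMASS"})
    with pytest.raises(InputError, match="biomass"):
        apply_genotype(allocation_model, g)


def test_leak_without_exchange_rejected(allocation_model):
    g = fg.Genotype(label="x", leaky={"prec": 1.0})
    with pytest.raises(InputError, match="exchange"):
        apply_genotype(allocation_model, g)


def test_unknown_gene_rejected(allocation_model):
    with pytest.raises(InputError, match="unknown genes"):
        fg.from_gene_deletions(allocation_model, {"nope"})


def test_gene_union_and_shared_mappings():
    model = fg.make_two_amino_acid_model(coupling="pleiotropy")
    g = fg.from_gene_deletions(model, {"genA", "genB"})
    assert g.deleted_reactions == {"SYN_A", "SYN_B1", "SYN_B2"}
    # a reaction mapped by a deleted gene is removed even if another gene
    # also maps to it
    shared = fg.MetabolicNetwork(
        metabolites=("A", "B"),
        reactions=("EX_A", "R", "BIOMASS"),
        stoich={("A", "EX_A"): -1.0, ("A", "R"): -1.0, ("B", "R"): 1.0, ("B", "BIOMASS"): -1.0},
        lower_bound={"EX_A": -10.0, "R": 0.0, "BIOMASS": 0.0},
        upper_bound={"EX_A": 0.0, "R": 1000.0, "BIOMASS": 1000.0},
        biomass_reaction="BIOMASS",
        exchanges={"A": "EX_A"},
        gene_map={"g1": {"R"}, "g2": {"R"}},
    )
    assert fg.from_gene_deletions(shared, {"g1"}).deleted_reactions == {"R"}
    assert genotype_fba(shared, fg.from_gene_deletions(shared, {"g1"})).biomass_flux == 0.0


# --------------------------------------------------------------------- #
# max sustainable leakiness
# --------------------------------------------------------------------- #
def test_emax_matches_closed_form_allocation_bound(allocation_model):
    g = fg.Genotype(label="WT")
    e_max = max_sustainable_leakiness(
        allocation_model, g, "aaA", tol=1e-4, viability_threshold=0.0
    )
    assert e_max == pytest.approx(10.0, abs=1e-4)


def test_emax_bisection_contract(allocation_model):
    g = fg.Genotype(label="WT")
    coarse = max_sustainable_leakiness(allocation_model, g, "aaA", tol=2e-3)
    fine = max_sustainable_leakiness(allocation_model, g, "aaA", tol=1e-3)
    assert abs(fine - coarse) <= 2e-3


def test_emax_bracketing(allocation_model):
    g = fg.Genotype(label="WT")
    tol = 1e-4
    e_max = max_sustainable_leakiness(allocation_model, g, "aaA", tol=tol)
    ok = genotype_fba(
        allocation_model, fg.Genotype(label="WT", leaky={"aaA": e_max})
    )
    assert ok.optimal and ok.biomass_flux >= fg.VIABILITY_THRESHOLD
    beyond = genotype_fba(
        allocation_model, fg.Genotype(label="WT", leaky={"aaA": e_max + 2 * tol})
    )
    assert (not beyond.optimal) or beyond.biomass_flux < fg.VIABILITY_THRESHOLD


def test_emax_zero_for_non_producible_metabolite(allocation_model):
    g = fg.from_gene_deletions(allocation_model, {"synA"}, label="noA")
    e_max = max_sustainable_leakiness(allocation_model, g, "aaA", tol=1e-4)
    assert e_max == pytest.approx(0.0, abs=1e-4)


def test_emax_errors_for_nonviable_genotype(amino_system):
    g00 = amino_system.genotype("00")
    with pytest.raises(InputError, match="no sustainable leakiness"):
        max_sustainable_leakiness(amino_system.model, g00, "aaA")


def test_payoff_monotone_in_own_leak_and_partner_supply(amino_system):
    model = amino_system.model
    values = []
    for e in (0.0, 1.0, 2.0, 3.0):
        res = genotype_fba(model, fg.Genotype(label="11", leaky={"aaA": e}))
        values.append(res.biomass_flux if res.optimal else -1.0)
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    g01 = amino_system.genotype("01")  # A auxotroph
    supplied = []
    for u in (0.5, 1.0, 2.0):
        res = genotype_fba(model, g01, extra_supply={"aaA": u})
        supplied.append(res.biomass_flux if res.optimal else -1.0)
    assert all(b >= a - 1e-9 for a, b in zip(supplied, supplied[1:]))
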