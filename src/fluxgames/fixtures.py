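"""Synthetic metabolic study systems and canonical games.

Three fixture families structurally emulate the biological systems the
package is designed around, at a scale where every payoff has a
hand-checkable LP oracle:

* a sucrose/invertase public-good system (producer pays an ATP cost ``x``
  per hydrolysis; a fraction ``e`` of the hexose product diffuses away as a
  public good; a non-producer mutant can only consume the public pool);
* a two-amino-acid biosynthesis system with the four genotypes 11, 01, 10,
  00 (digits = presence of the A and B pathways) and optional pathway
  coupling: ``pleiotropy`` (the A pathway consumes an intracellular
  intermediate of the B pathway, so losing B also abolishes A) and
  ``epistasis`` (both pathways co-produce a biomass side-compound that the
  double mutant must replace through an expensive salvage route);
* random viable networks for property tests.

All stoichiometries use small integer coefficients and a single carbon
source.  The sucrose system uses two catabolic routes - an efficient,
capacity-limited one and an unbounded overflow route - so the growth return
on hexose is concave, which is what separates the cheater-invasion boundary
from the producer-viability boundary and lets all three canonical game
regions appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import InputError
from .genotypes import VIABILITY_THRESHOLD, Genotype, from_gene_deletions, max_sustainable_leakiness
from .model import DEFAULT_BOUND, MetabolicNetwork
from .nash import Game
from .payoffs import DEFAULT_DEATH_RATE, PayoffEngine, PayoffTensor, bimatrix


@dataclass(frozen=True)
class GameSystem:
    """A model plus genotypes plus the payoff-engine configuration.

    This is the unit a landscape scan evaluates per grid cell.
    """

    model: MetabolicNetwork
    genotypes: tuple
    exchange_rule: str = "net"
    medium: Mapping = field(default_factory=dict)
    producer: str | None = None
    nonproducer: str | None = None
    full_producer: str | None = None
    death_rate: float = DEFAULT_DEATH_RATE
    viability_threshold: float = VIABILITY_THRESHOLD

    def __post_init__(self):
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "medium", dict(self.medium))

    def genotype(self, label: str) -> Genotype:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise InputError(f"no genotype labelled {label!r}")

    def engine(self) -> PayoffEngine:
        return PayoffEngine(
            model=self.model,
            death_rate=self.death_rate,
            viability_threshold=self.viability_threshold,
            exchange_rule=self.exchange_rule,
            medium=self.medium,
        )

    def build_tensor(self, order: int = 2) -> PayoffTensor:
        return self.engine().build_payoff_tensor(list(self.genotypes), order=order)


# ---------------------------------------------------------------------- #
# sucrose / invertase public good
# ---------------------------------------------------------------------- #
def make_sucrose_model(
    atp_cost_x: float,
    public_fraction: float,
    sucrose_uptake: float = 10.0,
    cat1_capacity: float = 5.0,
) -> MetabolicNetwork:
    """The toy sucrose-hydrolysis network.

    One sucrose yields two hexoses; a fraction ``public_fraction`` of them
    enters the shared extracellular pool, the rest stays private.  Hydrolysis
    costs ``atp_cost_x`` ATP.  ATP comes from an efficient capacity-limited
    route (3 ATP/hexose, capacity ``cat1_capacity``) or an overflow route
    (1 ATP/hexose); biomass consumes one hexose and one ATP.
    """
    if atp_cost_x < 0:
        raise InputError("atp_cost_x must be >= 0")
    if not 0.0 <= public_fraction <= 1.0:
        raise InputError("public_fraction must lie in [0, 1]")
    e = float(public_fraction)
    return MetabolicNetwork(
        metabolites=("suc", "hexpub", "hex", "atp"),
        reactions=("EX_suc", "HYD", "UPT_hexpub", "EX_hexpub", "CAT1", "CAT2", "BIOMASS"),
        stoich={
            ("suc", "EX_suc"): -1.0,
            ("suc", "HYD"): -1.0,
            ("atp", "HYD"): -float(atp_cost_x),
            ("hex", "HYD"): 2.0 * (1.0 - e),
            ("hexpub", "HYD"): 2.0 * e,
            ("hexpub", "UPT_hexpub"): -1.0,
            ("hex", "UPT_hexpub"): 1.0,
            ("hexpub", "EX_hexpub"): -1.0,
            ("hex", "CAT1"): -1.0,
            ("atp", "CAT1"): 3.0,
            ("hex", "CAT2"): -1.0,
            ("atp", "CAT2"): 1.0,
            ("hex", "BIOMASS"): -1.0,
            ("atp", "BIOMASS"): -1.0,
        },
        lower_bound={
            "EX_suc": -float(sucrose_uptake),
            "HYD": 0.0,
            "UPT_hexpub": 0.0,
            "EX_hexpub": 0.0,
            "CAT1": 0.0,
            "CAT2": 0.0,
            "BIOMASS": 0.0,
        },
        upper_bound={
            "EX_suc": 0.0,
            "HYD": DEFAULT_BOUND,
            "UPT_hexpub": DEFAULT_BOUND,
            "EX_hexpub": DEFAULT_BOUND,
            "CAT1": float(cat1_capacity),
            "CAT2": DEFAULT_BOUND,
            "BIOMASS": DEFAULT_BOUND,
        },
        biomass_reaction="BIOMASS",
        exchanges={"suc": "EX_suc", "hexpub": "EX_hexpub"},
        gene_map={"SUC2": {"HYD"}},
    )


def make_sucrose_fixture(
    atp_cost_x: float = 1.0,
    public_fraction: float = 0.4,
    sucrose_uptake: float = 10.0,
    glucose_supplement: float = 0.0,
    cat1_capacity: float = 5.0,
) -> GameSystem:
    """Producer (WT, hydrolysis intact) vs non-producer (MT, *suc2* deleted).

    The WT leaks ``2 * public_fraction * sucrose_uptake`` hexose units into
    the public pool (the stoichiometric leak at full hydrolysis); the MT can
    only consume that pool.  ``glucose_supplement`` adds free hexose to the
    medium for every player (the supplemented-medium condition).  The fixture
    uses the ``gross`` exchange rule because leakage here is structural: a
    producer may recapture from the shared pool what its partner put in.
    """
    model = make_sucrose_model(atp_cost_x, public_fraction, sucrose_uptake, cat1_capacity)
    leak = 2.0 * public_fraction * sucrose_uptake
    # the producer hydrolyzes constitutively: full sucrose uptake is forced,
    # so the structural leak is unavoidable rather than a strategic choice
    wt = Genotype(
        label="WT",
        leaky={"hexpub": leak} if leak > 0 else {},
        extra_bounds={"EX_suc": (-float(sucrose_uptake), -float(sucrose_uptake))},
    )
    mt_del = from_gene_deletions(model, {"SUC2"}, label="MT")
    medium = {"hexpub": float(glucose_supplement)} if glucose_supplement > 0 else {}
    return GameSystem(
        model=model,
        genotypes=(wt, mt_del),
        exchange_rule="gross",
        medium=medium,
        producer="WT",
        nonproducer="MT",
        full_producer="WT",
    )


def sucrose_scan_factory(glucose_supplement: float = 0.0, **fixed) -> Callable:
    """Factory for scans over ``atp_cost_x`` and ``capture_efficiency_e``.

    The capture efficiency axis is the fraction of hexose the producer keeps
    (1 - public fraction), matching the phase-diagram axes of the yeast
    system.
    """

    def factory(atp_cost_x: float, capture_efficiency_e: float) -> GameSystem:
        return make_sucrose_fixture(
            atp_cost_x=atp_cost_x,
            public_fraction=1.0 - capture_efficiency_e,
            glucose_supplement=glucose_supplement,
            **fixed,
        )

    return factory


# ---------------------------------------------------------------------- #
# two-amino-acid biosynthesis
# ---------------------------------------------------------------------- #
def make_two_amino_acid_model(
    cost_A: float = 1.0,
    cost_B: float = 1.0,
    coupling: str = "none",
    carbon_uptake: float = 10.0,
    side_cost: float = 6.0,
) -> MetabolicNetwork:
    """Carbon -> precursor -> {amino acid A, amino acid B} -> biomass.

    ``coupling="pleiotropy"`` routes A synthesis through an intracellular,
    non-exchangeable intermediate of the B pathway; ``coupling="epistasis"``
    makes both pathways co-produce an essential side compound that an
    uncoupled salvage reaction can replace only at ``side_cost`` ATP.
    """
    if cost_A <= 0 or cost_B <= 0:
        raise InputError("amino acid costs must be positive")
    if coupling not in ("none", "pleiotropy", "epistasis"):
        raise InputError(f"unknown coupling {coupling!r}")

    mets = ["carb", "prec", "aaA", "aaB", "atp"]
    stoich = {
        ("carb", "EX_carb"): -1.0,
        ("carb", "ANA"): -1.0,
        ("prec", "ANA"): 1.0,
        ("carb", "CAT"): -1.0,
        ("atp", "CAT"): 2.0,
        ("prec", "BIOMASS"): -1.0,
        ("aaA", "BIOMASS"): -1.0,
        ("aaB", "BIOMASS"): -1.0,
        ("atp", "BIOMASS"): -1.0,
        ("aaA", "EX_A"): -1.0,
        ("aaB", "EX_B"): -1.0,
    }
    reactions = ["EX_carb", "ANA", "CAT", "BIOMASS", "EX_A", "EX_B"]
    genes = {}

    if coupling == "pleiotropy":
        mets.append("bint")
        reactions += ["SYN_B1", "SYN_B2", "SYN_A"]
        stoich.update(
            {
                ("prec", "SYN_B1"): -1.0,
                ("atp", "SYN_B1"): -float(cost_B),
                ("bint", "SYN_B1"): 1.0,
                ("bint", "SYN_B2"): -1.0,
                ("aaB", "SYN_B2"): 1.0,
                ("bint", "SYN_A"): -1.0,
                ("atp", "SYN_A"): -float(cost_A),
                ("aaA", "SYN_A"): 1.0,
            }
        )
        genes = {"genA": {"SYN_A"}, "genB": {"SYN_B1", "SYN_B2"}}
    else:
        reactions += ["SYN_A", "SYN_B"]
        stoich.update(
            {
                ("prec", "SYN_A"): -1.0,
                ("atp", "SYN_A"): -float(cost_A),
                ("aaA", "SYN_A"): 1.0,
                ("prec", "SYN_B"): -1.0,
                ("atp", "SYN_B"): -float(cost_B),
                ("aaB", "SYN_B"): 1.0,
            }
        )
        genes = {"genA": {"SYN_A"}, "genB": {"SYN_B"}}
        if coupling == "epistasis":
            mets.append("sideS")
            reactions += ["SIDE_ALT", "DEG_S"]
            stoich.update(
                {
                    ("sideS", "SYN_A"): 1.0,
                    ("sideS", "SYN_B"): 1.0,
                    ("prec", "SIDE_ALT"): -1.0,
                    ("atp", "SIDE_ALT"): -float(side_cost),
                    ("sideS", "SIDE_ALT"): 1.0,
                    ("sideS", "DEG_S"): -1.0,
                    ("sideS", "BIOMASS"): -1.0,
                }
            )

    lb = {r: 0.0 for r in reactions}
    ub = {r: DEFAULT_BOUND for r in reactions}
    lb["EX_carb"], ub["EX_carb"] = -float(carbon_uptake), 0.0
    return MetabolicNetwork(
        metabolites=mets,
        reactions=reactions,
        stoich=stoich,
        lower_bound=lb,
        upper_bound=ub,
        biomass_reaction="BIOMASS",
        exchanges={"carb": "EX_carb", "aaA": "EX_A", "aaB": "EX_B"},
        gene_map=genes,
    )


def amino_acid_genotypes(
    model: MetabolicNetwork, leak_A: float, leak_B: float
) -> tuple:
    """The four genotypes 11, 01, 10, 00 at absolute leak fluxes.

    Digit 1/2 encodes presence of the A/B biosynthesis pathway; a genotype
    leaks only what it can synthesize.
    """

    def leaks(a: bool, b: bool) -> dict:
        out = {}
        if a and leak_A > 0:
            out["aaA"] = float(leak_A)
        if b and leak_B > 0:
            out["aaB"] = float(leak_B)
        return out

    g11 = Genotype(label="11", leaky=leaks(True, True))
    g01 = Genotype(
        label="01",
        deleted_reactions=from_gene_deletions(model, {"genA"}).deleted_reactions,
        leaky=leaks(False, True),
    )
    g10 = Genotype(
        label="10",
        deleted_reactions=from_gene_deletions(model, {"genB"}).deleted_reactions,
        leaky=leaks(True, False),
    )
    g00 = Genotype(
        label="00",
        deleted_reactions=from_gene_deletions(model, {"genA", "genB"}).deleted_reactions,
    )
    return (g11, g01, g10, g00)


def max_leak_fluxes(model: MetabolicNetwork) -> tuple:
    """(e_max_A, e_max_B): the full producer's maximum sustainable leak of
    each amino acid, the other one not leaked."""
    wt = Genotype(label="11")
    return (
        max_sustainable_leakiness(model, wt, "aaA"),
        max_sustainable_leakiness(model, wt, "aaB"),
    )


def make_two_amino_acid_fixture(
    cost_A: float = 1.0,
    cost_B: float = 1.0,
    coupling: str = "none",
    leakiness_A: float = 50.0,
    leakiness_B: float = 50.0,
    carbon_uptake: float = 10.0,
    side_cost: float = 6.0,
) -> GameSystem:
    """Two-amino-acid system at leakiness levels given in % of e_max."""
    model = make_two_amino_acid_model(cost_A, cost_B, coupling, carbon_uptake, side_cost)
    e_max_A, e_max_B = max_leak_fluxes(model)
    return GameSystem(
        model=model,
        genotypes=amino_acid_genotypes(
            model, leakiness_A / 100.0 * e_max_A, leakiness_B / 100.0 * e_max_B
        ),
        exchange_rule="net",
        full_producer="11",
    )


def amino_scan_factory(
    cost_A: float = 1.0,
    cost_B: float = 1.0,
    coupling: str = "none",
    carbon_uptake: float = 10.0,
    side_cost: float = 6.0,
) -> Callable:
    """Factory for scans over ``leakiness_A`` and ``leakiness_B`` (in %).

    The model and the per-amino-acid maximum sustainable leak fluxes are
    computed once and shared across all grid cells.
    """
    model = make_two_amino_acid_model(cost_A, cost_B, coupling, carbon_uptake, side_cost)
    e_max_A, e_max_B = max_leak_fluxes(model)

    def factory(leakiness_A: float, leakiness_B: float) -> GameSystem:
        return GameSystem(
            model=model,
            genotypes=amino_acid_genotypes(
                model, leakiness_A / 100.0 * e_max_A, leakiness_B / 100.0 * e_max_B
            ),
            exchange_rule="net",
            full_producer="11",
        )

    return factory


# ---------------------------------------------------------------------- #
# random viable networks
# ---------------------------------------------------------------------- #
def make_random_viable_fixture(
    n_metabolites: int = 8, n_reactions: int = 12, seed: int = 0
) -> MetabolicNetwork:
    """A random sparse network guaranteed viable by construction.

    A linear backbone (carbon uptake -> conversion chain -> biomass) ensures
    a feasible biomass-producing flux; extra random reactions consume one or
    two metabolites and produce one, so total mass never increases and the
    LP stays bounded.  Reproducible given the seed.
    """
    if n_metabolites < 3 or n_reactions < n_metabolites + 1:
        raise InputError("need >= 3 metabolites and >= n_metabolites + 1 reactions")
    rng = np.random.default_rng(seed)
    mets = [f"m{i}" for i in range(n_metabolites)]
    stoich, lb, ub, reactions = {}, {}, {}, []

    def add(rid, coeffs, lo=0.0, hi=DEFAULT_BOUND):
        reactions.append(rid)
        for m, s in coeffs.items():
            stoich[(m, rid)] = float(s)
        lb[rid], ub[rid] = float(lo), float(hi)

    add("EX_m0", {"m0": -1.0}, lo=-10.0, hi=0.0)
    for i in range(n_metabolites - 1):
        add(f"R{i}", {mets[i]: -1.0, mets[i + 1]: 1.0})
    add("BIOMASS", {mets[-1]: -1.0})
    n_extra = n_reactions - len(reactions)
    if n_extra < 0:
        raise InputError("n_reactions too small for the backbone")
    for k in range(n_extra):
        n_sub = int(rng.integers(1, 3))
        subs = rng.choice(n_metabolites, size=n_sub, replace=False)
        prod_choices = [i for i in range(n_metabolites) if i not in subs]
        prod = int(rng.choice(prod_choices))
        coeffs = {mets[int(s)]: -1.0 for s in subs}
        coeffs[mets[prod]] = 1.0
        add(f"X{k}", coeffs)
    return MetabolicNetwork(
        metabolites=mets,
        reactions=reactions,
        stoich=stoich,
        lower_bound=lb,
        upper_bound=ub,
        biomass_reaction="BIOMASS",
        exchanges={"m0": "EX_m0"},
        gene_map={},
    )


# ---------------------------------------------------------------------- #
# canonical textbook games
# ---------------------------------------------------------------------- #
def prisoners_dilemma() -> PayoffTensor:
    """Defection dominates although mutual cooperation pays more."""
    return bimatrix([[3.0, 0.0], [5.0, 1.0]], labels=("C", "D"))


def snowdrift() -> PayoffTensor:
    """Anti-coordination: the best response is to play the other strategy."""
    return bimatrix([[2.0, 1.0], [3.0, 0.0]], labels=("C", "D"))


def harmony() -> PayoffTensor:
    """Cooperation dominates (mutually beneficial)."""
    return bimatrix([[4.0, 2.0], [3.0, 1.0]], labels=("C", "D"))


def matching_pennies() -> Game:
    """Zero-sum game with no pure-strategy Nash equilibrium."""
    return Game.from_bimatrix(
        [[(1.0, -1.0), (-1.0, 1.0)], [(-1.0, 1.0), (1.0, -1.0)]],
        row_labels=("H", "T"),
        col_labels=("H", "T"),
    )
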