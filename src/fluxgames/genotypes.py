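"""Genotype-specific FBA problems: gene deletions, forced leakage, uptake.

A genotype is a strain defined by (i) a set of deleted reactions whose
fluxes are fixed to zero, (ii) leaky metabolites whose exchange flux is
forced to at least ``e_i`` (net export), and (iii) uptake allowances that
relax the exchange lower bound to ``-u_i``.

When a metabolite appears both as leaky and as supplied by partners, two
combination rules are offered (``exchange_rule``):

``"net"``
    Spec-literal reading: the binding lower bound is ``e_i`` (forced net
    export); partner supply of the same metabolite cannot be used.
``"gross"``
    Forced gross secretion with recapture of the shared pool:
    ``v_EX >= e_i - u_i``.  Appropriate when leakage is structural
    (stoichiometric), as in the sucrose public-good system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import InputError
from .model import FBAResult, MetabolicNetwork, solve_fba

#: biomass flux below which a genotype counts as non-viable (h^-1)
VIABILITY_THRESHOLD = 1e-6


@dataclass(frozen=True)
class Genotype:
    """A strain: deletions, forced secretion rates, uptake allowances.

    ``extra_bounds`` carries additional strain-specific flux bounds
    (``reaction -> (lb, ub)``), the generic hook for further environmental,
    strategic or genetic conditions - e.g. a constitutive uptake that makes
    a structural leak unavoidable.
    """

    label: str
    deleted_reactions: frozenset = field(default_factory=frozenset)
    leaky: Mapping = field(default_factory=dict)    # metabolite -> e_i >= 0
    uptakes: Mapping = field(default_factory=dict)  # metabolite -> u_i >= 0
    extra_bounds: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "deleted_reactions", frozenset(self.deleted_reactions))
        object.__setattr__(self, "leaky", {m: float(e) for m, e in dict(self.leaky).items()})
        object.__setattr__(self, "uptakes", {m: float(u) for m, u in dict(self.uptakes).items()})
        object.__setattr__(
            self,
            "extra_bounds",
            {r: (float(lo), float(hi)) for r, (lo, hi) in dict(self.extra_bounds).items()},
        )
        for m, e in self.leaky.items():
            if e < 0:
                raise InputError(f"negative leakage e_{m} = {e}")
        for m, u in self.uptakes.items():
            if u < 0:
                raise InputError(f"negative uptake allowance u_{m} = {u}")

    def check_against(self, model: MetabolicNetwork) -> None:
        unknown = self.deleted_reactions - set(model.reactions)
        if unknown:
            raise InputError(f"genotype {self.label!r} deletes unknown reactions {sorted(unknown)}")
        if model.biomass_reaction in self.deleted_reactions:
            raise InputError(f"genotype {self.label!r} deletes the biomass reaction")
        for m in list(self.leaky) + list(self.uptakes):
            if m not in model.exchanges:
                raise InputError(
                    f"genotype {self.label!r}: metabolite {m!r} has no exchange reaction"
                )
        unknown_rxns = set(self.extra_bounds) - set(model.reactions)
        if unknown_rxns:
            raise InputError(
                f"genotype {self.label!r}: extra bounds on unknown reactions "
                f"{sorted(unknown_rxns)}"
            )

    def signature(self) -> tuple:
        """Hashable identity of the FBA constraints this genotype induces."""
        return (
            tuple(sorted(self.deleted_reactions)),
            tuple(sorted(self.leaky.items())),
            tuple(sorted(self.uptakes.items())),
            tuple(sorted(self.extra_bounds.items())),
        )


def from_gene_deletions(model: MetabolicNetwork, genes, label: str | None = None) -> Genotype:
    """Build a genotype deleting the union of reactions mapped by ``genes``.

    A reaction is deleted if any deleted gene maps to it (plain set union,
    no boolean gene-protein-reaction logic).
    """
    genes = set(genes)
    unknown = genes - set(model.gene_map)
    if unknown:
        raise InputError(f"unknown genes {sorted(unknown)}")
    deleted = set()
    for g in genes:
        deleted |= model.gene_map[g]
    return Genotype(
        label=label if label is not None else "d_" + "_".join(sorted(genes)),
        deleted_reactions=deleted,
    )


def apply_genotype(
    model: MetabolicNetwork,
    genotype: Genotype,
    extra_supply: Mapping | None = None,
    exchange_rule: str = "net",
) -> dict:
    """Translate a genotype into FBA bound overrides.

    Parameters
    ----------
    extra_supply:
        Metabolite availability provided by partners and/or the growth
        medium, added to the genotype's own uptake allowances.
    exchange_rule:
        ``"net"`` or ``"gross"`` (see module docstring).

    Returns
    -------
    dict
        ``reaction -> (lb, ub)`` overrides suitable for
        :func:`fluxgames.model.solve_fba`.
    """
    if exchange_rule not in ("net", "gross"):
        raise InputError(f"unknown exchange_rule {exchange_rule!r}")
    genotype.check_against(model)
    supply = dict(genotype.uptakes)
    for m, u in (extra_supply or {}).items():
        if m not in model.exchanges:
            raise InputError(f"supplied metabolite {m!r} has no exchange reaction")
        supply[m] = supply.get(m, 0.0) + float(u)

    overrides: dict = {r: (0.0, 0.0) for r in genotype.deleted_reactions}
    touched = set(genotype.leaky) | set(supply)
    for m in touched:
        ex = model.exchanges[m]
        if ex in overrides:  # deleted exchange stays deleted
            continue
        e = genotype.leaky.get(m, 0.0)
        u = supply.get(m, 0.0)
        if m in genotype.leaky:
            # "net": forced net export e_i regardless of partner supply;
            # "gross": forced gross secretion, shared pool recapturable
            lb = e - u if exchange_rule == "gross" else e
        else:
            lb = -u
        overrides[ex] = (lb, model.upper_bound[ex])
    for rxn, bnd in genotype.extra_bounds.items():
        if rxn not in genotype.deleted_reactions:  # deletions take precedence
            overrides[rxn] = bnd
    return overrides


def genotype_fba(
    model: MetabolicNetwork,
    genotype: Genotype,
    extra_supply: Mapping | None = None,
    exchange_rule: str = "net",
    extra_constraints: Mapping | None = None,
) -> FBAResult:
    """Solve the genotype-constrained FBA problem."""
    overrides = apply_genotype(model, genotype, extra_supply, exchange_rule)
    if extra_constraints:
        overrides.update(extra_constraints)
    return solve_fba(model, overrides)


def max_sustainable_leakiness(
    model: MetabolicNetwork,
    genotype: Genotype,
    metabolite: str,
    tol: float | None = None,
    viability_threshold: float = VIABILITY_THRESHOLD,
    exchange_rule: str = "net",
) -> float:
    """Largest forced net export ``e`` of ``metabolite`` keeping the genotype viable.

    Found by bisection: the genotype's FBA problem (with ``v_EX >= e`` on top
    of the genotype's other leaks) is feasible with biomass >= the viability
    threshold at the returned value and not at the returned value + ``tol``.
    A metabolite the genotype cannot (net) export gives 0.
    """
    if metabolite not in model.exchanges:
        raise InputError(f"metabolite {metabolite!r} has no exchange reaction")

    def viable(e: float) -> bool:
        g = Genotype(
            label=genotype.label,
            deleted_reactions=genotype.deleted_reactions,
            leaky={**genotype.leaky, metabolite: e},
            uptakes=genotype.uptakes,
        )
        res = genotype_fba(model, g, exchange_rule=exchange_rule)
        return res.optimal and res.biomass_flux >= viability_threshold

    if not viable(0.0):
        raise InputError(
            f"genotype {genotype.label!r} is not viable at zero leakiness: "
            "no sustainable leakiness"
        )

    # bracket: grow exponentially from the total uptake capacity scale
    lb_arr, _ = model.bounds_arrays()
    uptake_capacity = float(sum(-b for b in lb_arr if b < 0)) or 1.0
    max_stoich = max((abs(s) for s in model.stoich.values()), default=1.0)
    hi = max(uptake_capacity * max_stoich, 1.0)
    lo = 0.0
    while viable(hi):
        lo = hi
        hi *= 2.0
        if hi > 1e9:
            raise InputError(
                f"leakiness of {metabolite!r} appears unbounded; check exchange bounds"
            )
    if tol is None:
        tol = 1e-4 * (hi - lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if viable(mid):
            lo = mid
        else:
            hi = mid
    return lo
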