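"""Stoichiometric metabolic networks and the flux balance analysis (FBA) LP.

FBA predicts steady-state reaction fluxes ``v`` by maximizing the flux of a
biomass pseudo-reaction subject to mass balance ``S v = 0`` and flux bounds
``LB <= v <= UB``.  The optimal biomass flux (h^-1) is used throughout the
package as a genotype's fitness proxy.

Sign convention for exchange reactions: each exchange reaction has a single
nonzero stoichiometric entry of -1 for its metabolite, so positive flux is
secretion and negative flux is uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import InputError, ModelValidationError, SolverError

#: default bound magnitude for effectively unconstrained fluxes
DEFAULT_BOUND = 1000.0
#: feasibility tolerance used in post-hoc mass-balance / bound checks
CHECK_TOL = 1e-6


@dataclass(frozen=True)
class MetabolicNetwork:
    """An immutable stoichiometric model.

    Parameters
    ----------
    metabolites, reactions:
        Ordered identifier tuples (sets I and J).
    stoich:
        Sparse map ``(metabolite, reaction) -> coefficient``.
    lower_bound, upper_bound:
        Flux bounds per reaction, mmol gDW^-1 h^-1.
    biomass_reaction:
        The reaction whose flux is maximized by FBA.
    exchanges:
        Map ``metabolite -> exchange reaction id``; each exchange reaction
        must have exactly one nonzero stoichiometric entry (-1 by convention).
    gene_map:
        Map ``gene -> set of reaction ids`` (plain many-to-many mapping,
        no boolean gene-protein-reaction logic).
    """

    metabolites: tuple
    reactions: tuple
    stoich: Mapping
    lower_bound: Mapping
    upper_bound: Mapping
    biomass_reaction: str
    exchanges: Mapping = field(default_factory=dict)
    gene_map: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "stoich", dict(self.stoich))
        object.__setattr__(self, "lower_bound", dict(self.lower_bound))
        object.__setattr__(self, "upper_bound", dict(self.upper_bound))
        object.__setattr__(self, "exchanges", dict(self.exchanges))
        object.__setattr__(
            self, "gene_map", {g: frozenset(r) for g, r in dict(self.gene_map).items()}
        )
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` listing every violated invariant."""
        problems = []
        mets, rxns = set(self.metabolites), set(self.reactions)
        if len(mets) != len(self.metabolites):
            problems.append("duplicate metabolite ids")
        if len(rxns) != len(self.reactions):
            problems.append("duplicate reaction ids")
        if self.biomass_reaction not in rxns:
            problems.append(f"biomass_reaction {self.biomass_reaction!r} not in reactions")
        for j in self.reactions:
            lb, ub = self.lower_bound.get(j), self.upper_bound.get(j)
            if lb is None or ub is None:
                problems.append(f"reaction {j!r} missing bounds")
            elif lb > ub:
                problems.append(f"reaction {j!r} has LB {lb} > UB {ub}")
        for (i, j) in self.stoich:
            if i not in mets:
                problems.append(f"stoich references unknown metabolite {i!r}")
            if j not in rxns:
                problems.append(f"stoich references unknown reaction {j!r}")
        for met, ex in self.exchanges.items():
            if met not in mets:
                problems.append(f"exchange for unknown metabolite {met!r}")
            elif ex not in rxns:
                problems.append(f"exchange reaction {ex!r} not in reactions")
            else:
                entries = [m for (m, j) in self.stoich if j == ex and self.stoich[(m, j)] != 0]
                if entries != [met]:
                    problems.append(
                        f"exchange reaction {ex!r} must have exactly one nonzero "
                        f"stoichiometric entry for {met!r}"
                    )
        for g, rs in self.gene_map.items():
            unknown = rs - rxns
            if unknown:
                problems.append(f"gene {g!r} maps to unknown reactions {sorted(unknown)}")
        if problems:
            raise ModelValidationError(problems)

    # ------------------------------------------------------------------ #
    def stoich_matrix(self) -> sparse.csr_matrix:
        """The |I| x |J| stoichiometric matrix as a CSR sparse matrix."""
        mi = {m: i for i, m in enumerate(self.metabolites)}
        ri = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for (m, r), s in self.stoich.items():
            if s != 0:
                rows.append(mi[m])
                cols.append(ri[r])
                vals.append(float(s))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.lower_bound[j] for j in self.reactions], dtype=float)
        ub = np.array([self.upper_bound[j] for j in self.reactions], dtype=float)
        return lb, ub

    def reaction_index(self, rxn: str) -> int:
        try:
            return self.reactions.index(rxn)
        except ValueError:
            raise InputError(f"unknown reaction id {rxn!r}") from None


@dataclass(frozen=True)
class FBAResult:
    """Outcome of one FBA solve.

    ``status`` is one of ``"optimal"``, ``"infeasible"``, ``"unbounded"``;
    ``biomass_flux`` and ``fluxes`` are defined only when optimal.
    """

    status: str
    biomass_flux: float | None = None
    fluxes: Mapping | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _merged_bounds(model: MetabolicNetwork, extra_constraints) -> list[tuple[float, float]]:
    """Apply bound overrides/fixings on top of the model's bounds.

    ``extra_constraints`` maps reaction id to ``(lb, ub)`` (either may be
    ``None`` to keep the model's value) or to a single number, which fixes
    the flux at that value.
    """
    lb, ub = model.bounds_arrays()
    bounds = list(zip(lb, ub))
    if not extra_constraints:
        return bounds
    for rxn, bnd in dict(extra_constraints).items():
        j = model.reaction_index(rxn)
        if np.isscalar(bnd):
            bounds[j] = (float(bnd), float(bnd))
        else:
            new_lb, new_ub = bnd
            cur_lb, cur_ub = bounds[j]
            bounds[j] = (
                cur_lb if new_lb is None else float(new_lb),
                cur_ub if new_ub is None else float(new_ub),
            )
    return bounds


def solve_fba(model: MetabolicNetwork, extra_constraints=None) -> FBAResult:
    """Maximize the biomass flux subject to ``S v = 0`` and flux bounds.

    Parameters
    ----------
    model:
        A validated :class:`MetabolicNetwork`.
    extra_constraints:
        Optional map ``reaction -> (lb, ub)`` overriding bounds, or
        ``reaction -> value`` fixing a flux (used for gene deletions,
        forced leakage and uptake allowances).

    Returns
    -------
    FBAResult
        With ``status="infeasible"`` when no flux vector satisfies the
        constraints, ``"unbounded"`` when the biomass flux is unbounded
        above (signals a missing exchange bound), else the optimum.
    """
    bounds = _merged_bounds(model, extra_constraints)
    for (blo, bup), j in zip(bounds, model.reactions):
        if blo > bup:
            return FBAResult(status="infeasible")
    S = model.stoich_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index(model.biomass_reaction)] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    if res.status == 2:
        return FBAResult(status="infeasible")
    if res.status == 3:
        return FBAResult(status="unbounded")
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}")
    fluxes = {j: float(v) for j, v in zip(model.reactions, res.x)}
    return FBAResult(
        status="optimal",
        biomass_flux=float(-res.fun),
        fluxes=fluxes,
    )


def check_solution(model: MetabolicNetwork, result: FBAResult, tol: float = CHECK_TOL) -> bool:
    """Post-hoc verification that an optimal flux vector is mass balanced
    and within bounds to ``tol``."""
    if not result.optimal:
        raise InputError("can only check an optimal FBAResult")
    v = np.array([result.fluxes[j] for j in model.reactions])
    balance = model.stoich_matrix() @ v
    lb, ub = model.bounds_arrays()
    return bool(
        np.all(np.abs(balance) <= tol)
        and np.all(v >= lb - tol)
        and np.all(v <= ub + tol)
    )
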