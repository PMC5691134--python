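"""Reading and writing models, genotypes and payoff tensors.

The canonical interchange format is a small JSON schema::

    {
      "metabolites": ["A", "B", ...],
      "reactions": [{"id": "R1", "stoich": {"A": -1, "B": 1},
                     "lb": 0, "ub": 1000}, ...],
      "biomass": "BIOMASS",
      "exchanges": {"A": "EX_A", ...},
      "genes": {"g1": ["R1"], ...}
    }

SBML Level 3 import (best effort) goes through cobra: species map to
metabolites, reactions carry FBC bounds when present (else +/-1000), and the
objective reaction becomes the biomass reaction.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import InputError, ModelValidationError
from .model import DEFAULT_BOUND, MetabolicNetwork

_REQUIRED_KEYS = ("metabolites", "reactions", "biomass")


def model_to_dict(model: MetabolicNetwork) -> dict:
    reactions = []
    for j in model.reactions:
        stoich = {
            m: model.stoich[(m, j)]
            for m in model.metabolites
            if (m, j) in model.stoich and model.stoich[(m, j)] != 0
        }
        reactions.append(
            {
                "id": j,
                "stoich": stoich,
                "lb": model.lower_bound[j],
                "ub": model.upper_bound[j],
            }
        )
    return {
        "metabolites": list(model.metabolites),
        "reactions": reactions,
        "biomass": model.biomass_reaction,
        "exchanges": dict(model.exchanges),
        "genes": {g: sorted(rs) for g, rs in model.gene_map.items()},
    }


def model_from_dict(data: dict) -> MetabolicNetwork:
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise ModelValidationError([f"model JSON missing key {k!r}" for k in missing])
    stoich, lb, ub, rxn_ids = {}, {}, {}, []
    for rx in data["reactions"]:
        for k in ("id", "stoich", "lb", "ub"):
            if k not in rx:
                raise ModelValidationError(f"reaction entry missing key {k!r}: {rx}")
        rxn_ids.append(rx["id"])
        lb[rx["id"]] = float(rx["lb"])
        ub[rx["id"]] = float(rx["ub"])
        for m, s in rx["stoich"].items():
            stoich[(m, rx["id"])] = float(s)
    return MetabolicNetwork(
        metabolites=data["metabolites"],
        reactions=rxn_ids,
        stoich=stoich,
        lower_bound=lb,
        upper_bound=ub,
        biomass_reaction=data["biomass"],
        exchanges=data.get("exchanges", {}),
        gene_map={g: set(rs) for g, rs in data.get("genes", {}).items()},
    )


def write_model(model: MetabolicNetwork, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def _read_sbml(path) -> MetabolicNetwork:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    mets = [m.id for m in cm.metabolites]
    stoich, lb, ub, rxns = {}, {}, {}, []
    exchanges = {}
    for r in cm.reactions:
        rxns.append(r.id)
        lo = r.lower_bound if r.lower_bound is not None else -DEFAULT_BOUND
        hi = r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
        lb[r.id], ub[r.id] = float(lo), float(hi)
        for m, s in r.metabolites.items():
            stoich[(m.id, r.id)] = float(s)
        if len(r.metabolites) == 1 and next(iter(r.metabolites.values())) == -1:
            exchanges[next(iter(r.metabolites)).id] = r.id
    biomass = None
    try:
        objective = [r.id for r in cm.reactions if r.objective_coefficient]
        if objective:
            biomass = objective[0]
    except Exception:
        biomass = None
    if biomass is None:
        raise ModelValidationError("SBML model has no objective (biomass) reaction")
    gene_map = {g.id: {r.id for r in g.reactions} for g in cm.genes}
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        stoich=stoich,
        lower_bound=lb,
        upper_bound=ub,
        biomass_reaction=biomass,
        exchanges=exchanges,
        gene_map=gene_map,
    )


def read_model(path, format: str | None = None) -> MetabolicNetwork:
    """Read a model from ``path``; ``format`` is ``"json"`` or ``"sbml"``
    (guessed from the suffix when omitted)."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"not valid JSON: {exc}") from exc
        return model_from_dict(data)
    if format == "sbml":
        return _read_sbml(path)
    raise InputError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------- #
# genotype JSON
# ---------------------------------------------------------------------- #
def genotype_to_dict(genotype) -> dict:
    out = {
        "label": genotype.label,
        "deleted_reactions": sorted(genotype.deleted_reactions),
        "leaky": dict(genotype.leaky),
        "uptakes": dict(genotype.uptakes),
    }
    if genotype.extra_bounds:
        out["extra_bounds"] = {r: list(b) for r, b in genotype.extra_bounds.items()}
    return out


def genotype_from_dict(data: dict, model: MetabolicNetwork | None = None):
    from .genotypes import Genotype, from_gene_deletions

    label = data.get("label", "?")
    if "deleted_genes" in data:
        if model is None:
            raise InputError("deleted_genes requires a model with a gene map")
        g = from_gene_deletions(model, set(data["deleted_genes"]), label=label)
        deleted = set(g.deleted_reactions) | set(data.get("deleted_reactions", ()))
    else:
        deleted = set(data.get("deleted_reactions", ()))
    return Genotype(
        label=label,
        deleted_reactions=deleted,
        leaky=data.get("leaky", {}),
        uptakes=data.get("uptakes", {}),
        extra_bounds={r: tuple(b) for r, b in data.get("extra_bounds", {}).items()},
    )


def read_genotypes(path, model: MetabolicNetwork | None = None) -> list:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [genotype_from_dict(d, model) for d in data]


def write_genotypes(genotypes, path) -> None:
    Path(path).write_text(json.dumps([genotype_to_dict(g) for g in genotypes], indent=1))
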