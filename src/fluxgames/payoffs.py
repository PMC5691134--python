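"""Payoff matrices and tensors for n-player microbial games.

The payoff of genotype ``k`` facing opponents ``(k', k'', ...)`` is the
optimal biomass flux of ``k``'s FBA problem in which every metabolite leaked
by the opponents is made available for uptake.  An infeasible problem, or a
feasible one whose biomass falls below the viability threshold, yields the
death rate (a negative constant) instead: such profiles are non-viable for
that player.

Entries are stored focal-first: ``entries[(k, k')]`` is ``a_kk'``, the payoff
of the first label when facing the rest.  For an order-n game all ``K**n``
ordered tuples are present.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import VIABILITY_THRESHOLD, Genotype, genotype_fba
from .model import MetabolicNetwork

#: payoff assigned to infeasible / sub-threshold problems (h^-1)
DEFAULT_DEATH_RATE = -0.05


@dataclass(frozen=True)
class PayoffTensor:
    """Payoffs for every ordered strategy profile of an n-player game."""

    players: tuple            # strategy labels, identical for every slot
    order: int                # number of players n >= 2
    entries: Mapping          # (focal, partner_1, ..., partner_{n-1}) -> payoff
    death_rate: float = DEFAULT_DEATH_RATE

    def __post_init__(self):
        object.__setattr__(self, "players", tuple(self.players))
        object.__setattr__(self, "entries", dict(self.entries))
        if self.order < 2:
            raise InputError("game order must be >= 2")
        expected = len(self.players) ** self.order
        if len(self.entries) != expected:
            raise InputError(
                f"payoff tensor incomplete: {len(self.entries)} entries, "
                f"expected {expected}"
            )
        for key in self.entries:
            if len(key) != self.order or any(k not in self.players for k in key):
                raise InputError(f"bad payoff tensor key {key!r}")

    # ------------------------------------------------------------------ #
    @property
    def n_strategies(self) -> int:
        return len(self.players)

    def payoff(self, focal: str, *opponents: str) -> float:
        if len(opponents) != self.order - 1:
            raise InputError(f"expected {self.order - 1} opponents, got {len(opponents)}")
        return self.entries[(focal,) + tuple(opponents)]

    def profile_payoffs(self, profile: Sequence[str]) -> tuple:
        """Per-player payoffs at a full strategy profile (player order kept)."""
        profile = tuple(profile)
        if len(profile) != self.order:
            raise InputError(f"profile must have {self.order} strategies")
        out = []
        for m in range(self.order):
            partners = profile[:m] + profile[m + 1:]
            out.append(self.entries[(profile[m],) + partners])
        return tuple(out)

    def to_array(self) -> np.ndarray:
        """Focal-first dense array ``a[k, k', ...]`` indexed by player order."""
        K, n = self.n_strategies, self.order
        idx = {p: i for i, p in enumerate(self.players)}
        a = np.empty((K,) * n)
        for key, val in self.entries.items():
            a[tuple(idx[k] for k in key)] = val
        return a

    def is_viable(self, payoff: float) -> bool:
        return payoff > self.death_rate

    def profile_viable(self, profile: Sequence[str]) -> bool:
        """True when every player in the profile grows (no death-rate payoff)."""
        return all(self.is_viable(p) for p in self.profile_payoffs(profile))

    # ------------------------------------------------------------------ #
    def to_json(self, path) -> None:
        data = {
            "players": list(self.players),
            "order": self.order,
            "death_rate": self.death_rate,
            "entries": {"|".join(k): v for k, v in self.entries.items()},
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PayoffTensor":
        data = json.loads(Path(path).read_text())
        return cls(
            players=data["players"],
            order=data["order"],
            entries={tuple(k.split("|")): float(v) for k, v in data["entries"].items()},
            death_rate=float(data.get("death_rate", DEFAULT_DEATH_RATE)),
        )

    def to_tsv(self, path) -> None:
        """Rows = focal strategy, columns = (ordered) opponent profile."""
        cols = list(itertools.product(self.players, repeat=self.order - 1))
        df = pd.DataFrame(
            [[self.entries[(p,) + c] for c in cols] for p in self.players],
            index=list(self.players),
            columns=["|".join(c) for c in cols],
        )
        df.index.name = "focal"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, death_rate: float = DEFAULT_DEATH_RATE) -> "PayoffTensor":
        # keep genotype labels like "01" as strings, not integers
        df = pd.read_csv(path, sep="\t", index_col=0, converters={0: str})
        df.columns = df.columns.map(str)
        players = list(df.index)
        entries = {}
        order = None
        for col in df.columns:
            opp = tuple(str(col).split("|"))
            order = len(opp) + 1
            for p in players:
                entries[(p,) + opp] = float(df.loc[p, col])
        if order is None:
            raise InputError("empty payoff table")
        return cls(players=players, order=order, entries=entries, death_rate=death_rate)


def bimatrix(row_payoffs, labels=("C", "D"), death_rate: float = DEFAULT_DEATH_RATE) -> PayoffTensor:
    """Build a symmetric 2-player tensor from a matrix of focal payoffs.

    ``row_payoffs[i][j]`` is the payoff of strategy ``labels[i]`` facing
    ``labels[j]`` (the textbook row-player convention).
    """
    labels = tuple(labels)
    a = np.asarray(row_payoffs, dtype=float)
    if a.shape != (len(labels), len(labels)):
        raise InputError("row_payoffs must be KxK for K labels")
    entries = {
        (labels[i], labels[j]): float(a[i, j])
        for i in range(len(labels))
        for j in range(len(labels))
    }
    return PayoffTensor(players=labels, order=2, entries=entries, death_rate=death_rate)


# ---------------------------------------------------------------------- #
@dataclass
class PayoffEngine:
    """Computes payoffs by genotype-specific FBA with caching.

    Parameters
    ----------
    model:
        The shared metabolic network (all genotypes are derived from it).
    death_rate:
        Payoff for infeasible or sub-threshold problems; must be < the
        viability threshold.
    viability_threshold:
        Minimum biomass flux (h^-1) counted as growth.
    exchange_rule:
        ``"net"`` (default) or ``"gross"``; see :mod:`fluxgames.genotypes`.
    medium:
        Metabolite availability provided by the environment to every player
        (e.g., supplemental glucose), added to partner-derived supply.
    aggregation:
        How multiple partners' leaks combine: ``"sum"`` (u_i = sum of
        partners' e_i; default) or ``"split"`` (each partner's leak divided
        evenly among the n-1 co-players).
    """

    model: MetabolicNetwork
    death_rate: float = DEFAULT_DEATH_RATE
    viability_threshold: float = VIABILITY_THRESHOLD
    exchange_rule: str = "net"
    medium: Mapping = field(default_factory=dict)
    aggregation: str = "sum"
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.death_rate >= self.viability_threshold:
            raise InputError("death_rate must lie below the viability threshold")
        if self.aggregation not in ("sum", "split"):
            raise InputError(f"unknown aggregation rule {self.aggregation!r}")

    # ------------------------------------------------------------------ #
    def _partner_supply(self, partners: Sequence[Genotype]) -> dict:
        supply = dict(self.medium)
        share = 1.0 if self.aggregation == "sum" else 1.0 / max(len(partners), 1)
        for p in partners:
            for m, e in p.leaky.items():
                supply[m] = supply.get(m, 0.0) + share * e
        return supply

    def payoff_against(self, focal: Genotype, partners: Sequence[Genotype]) -> float:
        """Payoff of ``focal`` facing ``partners`` (one independent FBA solve)."""
        supply = self._partner_supply(partners)
        key = (focal.signature(), tuple(sorted(supply.items())))
        if key not in self._cache:
            res = genotype_fba(
                self.model, focal, extra_supply=supply, exchange_rule=self.exchange_rule
            )
            if res.status == "unbounded":
                raise InputError(
                    f"FBA unbounded for genotype {focal.label!r}; check exchange bounds"
                )
            if res.optimal and res.biomass_flux >= self.viability_threshold:
                value = res.biomass_flux
            else:
                value = self.death_rate
            self._cache[key] = round(value, 9)
        return self._cache[key]

    def pairwise_payoff(self, k: Genotype, k_prime: Genotype) -> tuple:
        """Two independent FBA solves: (payoff of k facing k', payoff of k' facing k)."""
        return (self.payoff_against(k, [k_prime]), self.payoff_against(k_prime, [k]))

    def build_payoff_tensor(self, genotypes: Sequence[Genotype], order: int = 2) -> PayoffTensor:
        """Payoffs for every ordered profile of an ``order``-player game."""
        if order < 2:
            raise InputError("order must be >= 2")
        if not genotypes:
            raise InputError("need at least one genotype")
        labels = [g.label for g in genotypes]
        if len(set(labels)) != len(labels):
            raise InputError("genotype labels must be unique")
        by_label = {g.label: g for g in genotypes}
        entries = {}
        for key in itertools.product(labels, repeat=order):
            focal, partners = key[0], [by_label[k] for k in key[1:]]
            entries[key] = self.payoff_against(by_label[focal], partners)
        return PayoffTensor(
            players=labels, order=order, entries=entries, death_rate=self.death_rate
        )


def pairwise_payoff(model: MetabolicNetwork, k: Genotype, k_prime: Genotype, **kwargs) -> tuple:
    """Convenience wrapper around :meth:`PayoffEngine.pairwise_payoff`."""
    return PayoffEngine(model, **kwargs).pairwise_payoff(k, k_prime)


def build_payoff_tensor(
    model: MetabolicNetwork, genotypes: Sequence[Genotype], order: int = 2, **kwargs
) -> PayoffTensor:
    """Convenience wrapper around :meth:`PayoffEngine.build_payoff_tensor`."""
    return PayoffEngine(model, **kwargs).build_payoff_tensor(genotypes, order)
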