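"""Parameter-grid scans: game classification and equilibrium landscapes.

A scan sweeps a 2-D grid of parameters (e.g., leakiness of two amino acids
as a percentage of the full producer's maximum sustainable level, or the
ATP cost and capture efficiency of a public-good hydrolysis reaction),
builds the payoff tensor in each cell, enumerates the pure-strategy Nash
equilibria, and classifies 2-strategy producer/non-producer games into the
canonical cooperation games.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import VIABILITY_THRESHOLD
from .nash import NashResult, find_nash
from .payoffs import PayoffTensor

GAME_CLASS_LABELS = (
    "prisoners_dilemma",
    "snowdrift",
    "mutually_beneficial",
    "producer_dominance",
    "non_viable",
    "other",
)


@dataclass(frozen=True)
class GameClass:
    """A canonical-game label together with the Nash set that produced it."""

    label: str
    nash_profiles: tuple

    def __post_init__(self):
        if self.label not in GAME_CLASS_LABELS:
            raise InputError(f"unknown game class label {self.label!r}")
        object.__setattr__(self, "nash_profiles", tuple(self.nash_profiles))


def classify_game(
    nash: NashResult,
    tensor: PayoffTensor,
    producer: str | None = None,
    nonproducer: str | None = None,
) -> GameClass:
    """Classify a 2-strategy symmetric producer/non-producer game.

    With producer C and non-producer D:

    * ``non_viable``: every profile carries only death-rate payoffs;
    * ``snowdrift``: the two mixed profiles (C,D) and (D,C) are the stable
      outcomes (a_DC > a_CC and a_CD > a_DD);
    * ``mutually_beneficial``: (C,C) is Nash and (D,D) is not
      (a_CC >= a_DC and a_CD > a_DD);
    * ``prisoners_dilemma``: defection is the best response to everything
      although mutual production would pay both more
      (a_DC > a_CC, a_DD >= a_CD, a_CC > a_DD);
    * ``producer_dominance``: (C,C) is Nash while the non-producer is
      non-viable against every opponent;
    * ``other``: the remaining payoff orderings.

    The conditions are stated on payoff orderings; whenever the payoffs are
    non-degenerate they coincide with the Nash-set characterizations
    (snowdrift = {(C,D),(D,C)}, prisoners_dilemma = {(D,D)}, ...).  Stating
    them on orderings keeps the labels meaningful when dead strategies tie
    exactly at the death rate, where weak-Nash ties would otherwise blur the
    phase diagram.
    """
    if tensor.order != 2 or tensor.n_strategies != 2:
        raise InputError(
            "classify_game handles 2-strategy 2-player games; classify "
            "pairwise sub-games explicitly for larger tensors"
        )
    C = producer if producer is not None else tensor.players[0]
    D = nonproducer if nonproducer is not None else tensor.players[1]
    if {C, D} != set(tensor.players):
        raise InputError("producer/nonproducer labels must match the tensor players")

    a_cc, a_cd = tensor.payoff(C, C), tensor.payoff(C, D)
    a_dc, a_dd = tensor.payoff(D, C), tensor.payoff(D, D)
    all_dead = all(v <= tensor.death_rate for v in tensor.entries.values())

    if all_dead:
        label = "non_viable"
    elif a_dc > a_cc and a_cd > a_dd:
        label = "snowdrift"
    elif a_cc >= a_dc and a_cd > a_dd:
        label = "mutually_beneficial"
    elif a_dc > a_cc and a_dd >= a_cd and a_cc > a_dd:
        label = "prisoners_dilemma"
    elif a_cc >= a_dc and not tensor.is_viable(a_dc) and not tensor.is_viable(a_dd):
        label = "producer_dominance"
    else:
        label = "other"
    return GameClass(label=label, nash_profiles=nash.equilibria)


@dataclass(frozen=True)
class AxisSpec:
    """A named parameter axis with its grid values."""

    name: str
    values: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @classmethod
    def linspace(cls, name: str, lo: float, hi: float, n: int = 21) -> "AxisSpec":
        return cls(name, tuple(np.linspace(lo, hi, n)))


#: default leakiness axis, 0-100% of e_max in 5% steps (21 levels)
def leakiness_axis(name: str, n: int = 21) -> AxisSpec:
    return AxisSpec.linspace(name, 0.0, 100.0, n)


@dataclass(frozen=True)
class LandscapeCell:
    """Everything computed for one grid cell."""

    tensor: PayoffTensor
    nash: NashResult
    game_class: GameClass | None
    self_payoffs: Mapping        # label -> payoff of label facing itself

    def viable_nash(self) -> tuple:
        """Nash profiles at which every player grows."""
        return tuple(p for p in self.nash.equilibria if self.tensor.profile_viable(p))


@dataclass(frozen=True)
class Landscape:
    axis1: AxisSpec
    axis2: AxisSpec
    cells: Mapping                # (i, j) -> LandscapeCell
    players: tuple
    full_producer: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "cells", dict(self.cells))
        expected = {
            (i, j)
            for i in range(len(self.axis1.values))
            for j in range(len(self.axis2.values))
        }
        if set(self.cells) != expected:
            raise InputError("landscape grid has missing or extra cells")

    @property
    def shape(self) -> tuple:
        return (len(self.axis1.values), len(self.axis2.values))

    def class_grid(self) -> np.ndarray:
        out = np.full(self.shape, "", dtype=object)
        for (i, j), cell in self.cells.items():
            out[i, j] = cell.game_class.label if cell.game_class else ""
        return out

    def mask(self, predicate: Callable) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for (i, j), cell in self.cells.items():
            out[i, j] = bool(predicate(cell))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (i, j), cell in sorted(self.cells.items()):
            rows.append(
                {
                    self.axis1.name: self.axis1.values[i],
                    self.axis2.name: self.axis2.values[j],
                    "game_class": cell.game_class.label if cell.game_class else "",
                    "nash_profiles": json.dumps([list(p) for p in cell.nash.equilibria]),
                    "viable_nash_profiles": json.dumps(
                        [list(p) for p in cell.viable_nash()]
                    ),
                    "producer_viable": bool(
                        self.full_producer is not None
                        and cell.self_payoffs.get(self.full_producer, -np.inf)
                        >= VIABILITY_THRESHOLD
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def scan(
    factory: Callable,
    axis1: AxisSpec,
    axis2: AxisSpec,
    order: int = 2,
    method: str = "ilp",
) -> Landscape:
    """Evaluate a game system on every cell of a 2-D parameter grid.

    ``factory(**{axis1.name: v1, axis2.name: v2})`` must return a
    :class:`fluxgames.fixtures.GameSystem`; each cell gets its payoff tensor,
    Nash set and (for 2-strategy systems) game classification.  The result is
    deterministic given the factory and grid.
    """
    cells = {}
    players = None
    full_producer = None
    for (i, v1), (j, v2) in itertools.product(
        enumerate(axis1.values), enumerate(axis2.values)
    ):
        try:
            system = factory(**{axis1.name: v1, axis2.name: v2})
            tensor = system.build_tensor(order=order)
            nash = find_nash(tensor, method=method)
        except Exception as exc:
            raise InputError(
                f"scan failed at cell ({axis1.name}={v1}, {axis2.name}={v2}): {exc}"
            ) from exc
        players = tensor.players
        full_producer = system.full_producer
        game_class = None
        if tensor.n_strategies == 2 and order == 2:
            game_class = classify_game(
                nash, tensor, producer=system.producer, nonproducer=system.nonproducer
            )
        self_payoffs = {p: tensor.entries[(p,) * order] for p in tensor.players}
        cells[(i, j)] = LandscapeCell(
            tensor=tensor, nash=nash, game_class=game_class, self_payoffs=self_payoffs
        )
    return Landscape(
        axis1=axis1, axis2=axis2, cells=cells, players=players,
        full_producer=full_producer,
    )


def sustainable_region(landscape: Landscape, full_producer_label: str | None = None) -> np.ndarray:
    """Cells where the full producer still grows in self-play.

    This is the paper-style "sustainable leakiness region": the set of
    leakiness combinations at which the genotype leaking everything retains
    a biomass flux at or above the viability threshold.
    """
    label = full_producer_label or landscape.full_producer
    if label is None or label not in landscape.players:
        raise InputError(f"unknown full producer label {label!r}")
    return landscape.mask(
        lambda cell: cell.self_payoffs[label] >= VIABILITY_THRESHOLD
    )


def profile_region(landscape: Landscape, profile: Sequence[str], viable_only: bool = True) -> np.ndarray:
    """Cells where the unordered ``profile`` is a (viable) Nash equilibrium."""
    target = tuple(sorted(profile))

    def has_profile(cell) -> bool:
        pool = cell.viable_nash() if viable_only else cell.nash.equilibria
        return any(tuple(sorted(p)) == target for p in pool)

    return landscape.mask(has_profile)


def enumerate_amino_acid_pairs(amino_acids: Sequence[str], exclusions: Sequence = ()) -> list:
    """All unordered distinct pairs minus exclusions, lexicographically sorted.

    The 20 proteinogenic amino acids with one excluded pair give the 189
    pairs scanned in the two-amino-acid analyses.
    """
    amino_acids = list(amino_acids)
    if len(set(amino_acids)) != len(amino_acids):
        raise InputError("duplicate amino acid names")
    all_pairs = {tuple(sorted(p)) for p in itertools.combinations(amino_acids, 2)}
    excl = {tuple(sorted(e)) for e in exclusions}
    unknown = excl - all_pairs
    if unknown:
        raise InputError(f"exclusions not in the pair set: {sorted(unknown)}")
    return sorted(all_pairs - excl)


AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
#: pair excluded because its double mutant is auxotrophic for a third amino acid
EXCLUDED_PAIRS = (("Ala", "Ile"),)


def plot_landscape(landscape: Landscape, path=None, ax=None):
    """Optional heatmap of game classes (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = landscape.class_grid()
    labels = sorted({g for g in grid.ravel()})
    index = {lbl: i for i, lbl in enumerate(labels)}
    numeric = np.vectorize(index.get)(grid)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(numeric.T, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xlabel(landscape.axis1.name)
    ax.set_ylabel(landscape.axis2.name)
    cbar = ax.figure.colorbar(im, ax=ax, ticks=range(len(labels)))
    cbar.ax.set_yticklabels(labels)
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax
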