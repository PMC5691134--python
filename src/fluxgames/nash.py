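"""Enumeration of all pure-strategy Nash equilibria of an n-player game.

Two routes are provided and cross-checked in the test suite:

``find_nash_ilp``
    One binary indicator ``w`` per strategy profile; ``w = 1`` is feasible
    exactly when, for every player, the profile's payoff is at least the
    best unilateral deviation (weak inequality, big-M slack via a lower
    bound ``LB`` strictly below every payoff).  Maximizing ``sum(w)`` then
    flags every equilibrium in a single exact MIP solve.  An optimum of
    z = 0 means no pure-strategy Nash equilibrium exists (the all-zero
    solution is always feasible, so emptiness appears as z = 0 rather than
    infeasibility).

``brute_force_nash``
    Direct exhaustive deviation check over all profiles (the independent
    verification oracle).

Games may be asymmetric (distinct payoffs and strategy sets per player);
symmetric games built by the payoff engine are converted from their
focal-first tensor form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .errors import InputError, SolverError
from .payoffs import PayoffTensor


@dataclass(frozen=True)
class Game:
    """An n-player game in normal form.

    ``strategies[m]`` is the label tuple for player ``m``;
    ``payoffs[m][i1, ..., in]`` is player ``m``'s payoff at the profile
    whose players take strategies ``i1 ... in``.
    """

    strategies: tuple
    payoffs: tuple  # tuple of n ndarrays, each of shape (K1, ..., Kn)

    def __post_init__(self):
        object.__setattr__(self, "strategies", tuple(tuple(s) for s in self.strategies))
        arrays = tuple(np.asarray(a, dtype=float) for a in self.payoffs)
        object.__setattr__(self, "payoffs", arrays)
        shape = tuple(len(s) for s in self.strategies)
        for a in arrays:
            if a.shape != shape:
                raise InputError(f"payoff array shape {a.shape} != strategy shape {shape}")
            if not np.all(np.isfinite(a)):
                raise InputError("payoffs must be finite")

    @property
    def n_players(self) -> int:
        return len(self.strategies)

    @property
    def shape(self) -> tuple:
        return tuple(len(s) for s in self.strategies)

    def profile_labels(self, index: tuple) -> tuple:
        return tuple(self.strategies[m][i] for m, i in enumerate(index))

    # ------------------------------------------------------------------ #
    @classmethod
    def from_tensor(cls, tensor: PayoffTensor) -> "Game":
        """Expand a symmetric focal-first tensor into per-player payoff arrays."""
        a = tensor.to_array()
        n, K = tensor.order, tensor.n_strategies
        payoffs = []
        for m in range(n):
            # player m's payoff at profile p is a[p_m, p_others-in-order];
            # transpose semantics: out[idx] = a[idx[axes[0]], idx[axes[1]], ...]
            perm = (m,) + tuple(i for i in range(n) if i != m)
            payoffs.append(np.transpose(a, axes=perm))
        return cls(strategies=(tensor.players,) * n, payoffs=tuple(payoffs))

    @classmethod
    def from_bimatrix(cls, cells, row_labels=None, col_labels=None) -> "Game":
        """Build a two-player game from a matrix of (row payoff, col payoff) cells."""
        cells = [[tuple(c) for c in row] for row in cells]
        nr, nc = len(cells), len(cells[0])
        row_labels = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(nr))
        col_labels = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(nc))
        a1 = np.array([[c[0] for c in row] for row in cells], dtype=float)
        a2 = np.array([[c[1] for c in row] for row in cells], dtype=float)
        return cls(strategies=(row_labels, col_labels), payoffs=(a1, a2))


def as_game(game) -> Game:
    if isinstance(game, Game):
        return game
    if isinstance(game, PayoffTensor):
        return Game.from_tensor(game)
    raise InputError(f"expected a Game or PayoffTensor, got {type(game).__name__}")


@dataclass(frozen=True)
class NashResult:
    """The pure-strategy Nash equilibria of a game.

    ``equilibria`` holds label profiles; ``indicator`` maps every profile
    to its 0/1 Nash flag; ``payoff_bounds`` records the per-player big-M
    lower bounds used by the ILP (``None`` for the brute-force route).
    """

    equilibria: tuple
    indicator: dict
    payoff_bounds: tuple | None = None
    method: str = "ilp"

    @property
    def is_empty(self) -> bool:
        return len(self.equilibria) == 0

    def __contains__(self, profile) -> bool:
        return tuple(profile) in set(self.equilibria)


def _deviation_maxima(game: Game) -> list:
    """best_m[profile] = max over player m's unilateral deviations (incl. stay)."""
    return [
        np.broadcast_to(np.max(game.payoffs[m], axis=m, keepdims=True), game.shape)
        for m in range(game.n_players)
    ]


def brute_force_nash(game, tol: float = 1e-9) -> NashResult:
    """Exhaustive weak-Nash check: a profile is an equilibrium iff no player
    gains more than ``tol`` by any unilateral deviation."""
    game = as_game(game)
    best = _deviation_maxima(game)
    mask = np.ones(game.shape, dtype=bool)
    for m in range(game.n_players):
        mask &= game.payoffs[m] >= best[m] - tol
    indicator, equilibria = {}, []
    for index in itertools.product(*(range(k) for k in game.shape)):
        labels = game.profile_labels(index)
        flag = int(mask[index])
        indicator[labels] = flag
        if flag:
            equilibria.append(labels)
    return NashResult(
        equilibria=tuple(equilibria),
        indicator=indicator,
        payoff_bounds=None,
        method="brute",
    )


def find_nash_ilp(game) -> NashResult:
    """Enumerate all pure-strategy Nash equilibria via the indicator ILP.

    For every profile and player ``m`` the constraint

        ``a_m >= max_deviation_m * w + LB_m * (1 - w)``

    forces ``w = 0`` whenever the profile is not a best response for some
    player; maximizing ``sum(w)`` with an exact branch-and-bound MIP then
    sets ``w = 1`` for every equilibrium.  ``LB_m`` is chosen strictly below
    player ``m``'s minimum payoff so the constraint is slack at ``w = 0``.
    """
    game = as_game(game)
    n_profiles = int(np.prod(game.shape))
    best = _deviation_maxima(game)
    lbs = tuple(float(np.min(a) - 1.0 - abs(np.min(a))) for a in game.payoffs)

    rows, cols, vals, rhs = [], [], [], []
    r = 0
    for m in range(game.n_players):
        coeff = (best[m] - lbs[m]).ravel()        # > 0 by construction of LB
        bound = (game.payoffs[m] - lbs[m]).ravel()
        for p in range(n_profiles):
            rows.append(r)
            cols.append(p)
            vals.append(coeff[p])
            rhs.append(bound[p])
            r += 1
    A = csr_matrix((vals, (rows, cols)), shape=(r, n_profiles))
    res = milp(
        c=-np.ones(n_profiles),
        constraints=LinearConstraint(A, -np.inf, np.array(rhs)),
        integrality=np.ones(n_profiles),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"NashEq Finder MIP failed: {res.message}")
    w = res.x > 0.5

    indicator, equilibria = {}, []
    for flat, index in enumerate(itertools.product(*(range(k) for k in game.shape))):
        labels = game.profile_labels(index)
        indicator[labels] = int(w[flat])
        if w[flat]:
            equilibria.append(labels)
    return NashResult(
        equilibria=tuple(equilibria),
        indicator=indicator,
        payoff_bounds=lbs,
        method="ilp",
    )


def find_nash(game, method: str = "ilp") -> NashResult:
    if method == "ilp":
        return find_nash_ilp(game)
    if method == "brute":
        return brute_force_nash(game)
    raise InputError(f"unknown method {method!r}")


def random_game(rng: np.random.Generator, n_players: int, sizes) -> Game:
    """A random game with the given per-player strategy counts (test input)."""
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != n_players:
        raise InputError("sizes must have one entry per player")
    strategies = tuple(tuple(f"p{m}s{i}" for i in range(k)) for m, k in enumerate(sizes))
    payoffs = tuple(np.round(rng.normal(size=sizes), 6) for _ in range(n_players))
    return Game(strategies=strategies, payoffs=payoffs)
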