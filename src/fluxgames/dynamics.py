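"""Replicator dynamics, invasion experiments and selection coefficients.

The extended replicator equation drives genotype frequencies ``x_k``:

    dx_k/dt = (f_k(x) - phi(x)) x_k

where the fitness ``f_k`` sums the payoff contributions of every interaction
order present (pairwise: ``sum_k' a_kk' x_k'``; three-player:
``sum_k' sum_k'' a_kk'k'' x_k' x_k''``; ...), and ``phi = sum_k f_k x_k`` is
the community's mean fitness.  Frequencies live on the probability simplex,
which the dynamics preserve analytically; numerically we renormalize drift
only within 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputError
from .payoffs import PayoffTensor

SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class CommunityState:
    """Genotype frequencies on the simplex with their aligned labels."""

    frequencies: np.ndarray
    genotype_labels: tuple

    def __post_init__(self):
        x = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", x)
        object.__setattr__(self, "genotype_labels", tuple(self.genotype_labels))
        if x.ndim != 1 or len(x) != len(self.genotype_labels):
            raise InputError("frequencies and labels must align")
        if np.any(x < -SIMPLEX_TOL) or abs(x.sum() - 1.0) > 1e-6:
            raise InputError(f"frequencies not on the simplex: {x}")

    def as_dict(self) -> dict:
        return dict(zip(self.genotype_labels, map(float, self.frequencies)))

    def __getitem__(self, label: str) -> float:
        return float(self.frequencies[self.genotype_labels.index(label)])


@dataclass(frozen=True)
class Trajectory:
    """A replicator time course.

    ``equilibrium`` is the final :class:`CommunityState` when the dynamics
    converged (sup-norm of dx/dt below tolerance), else the string
    ``"not converged"``.
    """

    times: np.ndarray
    states: np.ndarray            # shape (n_times, K)
    genotype_labels: tuple
    equilibrium: object
    mean_fitness_series: np.ndarray

    @property
    def converged(self) -> bool:
        return isinstance(self.equilibrium, CommunityState)

    @property
    def final_state(self) -> CommunityState:
        return CommunityState(self.states[-1], self.genotype_labels)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.genotype_labels))
        df.insert(0, "time", self.times)
        df["mean_fitness"] = self.mean_fitness_series
        return df


def _tensor_list(tensors) -> list:
    if isinstance(tensors, PayoffTensor):
        return [tensors]
    tensors = list(tensors)
    if not tensors:
        raise InputError("need at least one payoff tensor")
    players = tensors[0].players
    for t in tensors:
        if t.players != players:
            raise InputError("all tensors must share the same genotype labels")
    return tensors


def fitness(x: np.ndarray, tensors) -> np.ndarray:
    """Per-genotype fitness f_k(x), summing all interaction orders supplied."""
    tensors = _tensor_list(tensors)
    x = np.asarray(x, dtype=float)
    K = len(tensors[0].players)
    if x.shape != (K,):
        raise InputError(f"frequency vector must have length {K}")
    f = np.zeros(K)
    for t in tensors:
        a = t.to_array()
        for _ in range(t.order - 1):
            a = a @ x
        f += a
    return f


def replicator_rhs(x: np.ndarray, tensors) -> np.ndarray:
    """dx/dt = (f(x) - phi(x)) * x for the supplied payoff tensor(s)."""
    x = np.asarray(x, dtype=float)
    f = fitness(x, tensors)
    phi = float(f @ x)
    return (f - phi) * x


def integrate(
    x0,
    tensors,
    t_max: float = 1000.0,
    tol: float = 1e-7,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    labels: Sequence[str] | None = None,
) -> Trajectory:
    """Integrate the replicator ODE with an adaptive Runge-Kutta scheme.

    Convergence is declared when the sup-norm of dx/dt drops below ``tol``
    (a terminal event of the integrator); otherwise the trajectory is
    returned with ``equilibrium = "not converged"``.
    """
    tensors = _tensor_list(tensors)
    genotype_labels = tuple(labels) if labels is not None else tensors[0].players
    x0 = np.asarray(x0, dtype=float)
    if abs(x0.sum() - 1.0) > 1e-6 or np.any(x0 < -SIMPLEX_TOL):
        raise InputError("x0 must lie on the probability simplex")
    x0 = np.clip(x0, 0.0, None)
    x0 = x0 / x0.sum()

    def rhs(t, x):
        # evaluate on the projected state: off-simplex drift is exponentially
        # unstable whenever the mean fitness is negative (death-rate payoffs),
        # and the projection keeps sum(dx/dt) = 0 exactly
        z = np.clip(x, 0.0, None)
        z = z / z.sum()
        return replicator_rhs(z, tensors)

    def settled(t, x):
        return float(np.max(np.abs(rhs(t, x)))) - tol

    settled.terminal = True
    settled.direction = -1

    if np.max(np.abs(replicator_rhs(x0, tensors))) < tol:
        states = np.array([x0])
        phi = np.array([float(fitness(x0, tensors) @ x0)])
        return Trajectory(
            times=np.array([0.0]),
            states=states,
            genotype_labels=genotype_labels,
            equilibrium=CommunityState(x0, genotype_labels),
            mean_fitness_series=phi,
        )

    sol = solve_ivp(
        rhs, (0.0, t_max), x0, method="RK45", rtol=rtol, atol=atol,
        events=settled, dense_output=False,
    )
    if not sol.success:
        raise InputError(f"replicator integration failed: {sol.message}")

    states = sol.y.T
    # drift off the simplex is renormalized only within tolerance
    sums = states.sum(axis=1)
    if np.max(np.abs(sums - 1.0)) > SIMPLEX_TOL * 10:
        raise InputError("replicator trajectory left the simplex beyond tolerance")
    states = np.clip(states, 0.0, None)
    states = states / states.sum(axis=1, keepdims=True)
    phi = np.array([float(fitness(x, tensors) @ x) for x in states])

    converged = sol.status == 1 or np.max(np.abs(replicator_rhs(states[-1], tensors))) < tol
    equilibrium = (
        CommunityState(states[-1], genotype_labels) if converged else "not converged"
    )
    return Trajectory(
        times=sol.t,
        states=states,
        genotype_labels=genotype_labels,
        equilibrium=equilibrium,
        mean_fitness_series=phi,
    )


def restrict_tensor(tensor: PayoffTensor, labels: Sequence[str]) -> PayoffTensor:
    """The sub-game among ``labels`` only."""
    labels = tuple(labels)
    unknown = set(labels) - set(tensor.players)
    if unknown:
        raise InputError(f"unknown genotype labels {sorted(unknown)}")
    import itertools

    entries = {
        key: tensor.entries[key]
        for key in itertools.product(labels, repeat=tensor.order)
    }
    return PayoffTensor(
        players=labels, order=tensor.order, entries=entries, death_rate=tensor.death_rate
    )


def invade(
    resident_labels: Sequence[str],
    invader_labels: Sequence[str],
    invasion_fraction: float,
    tensor: PayoffTensor,
    t_max: float = 1000.0,
    tol: float = 1e-7,
    resident_frequencies: Sequence[float] | None = None,
) -> Trajectory:
    """In silico invasion: low-frequency invaders enter a resident community.

    Residents are first equilibrated among themselves (replicator dynamics of
    the restricted sub-game from a uniform start) unless explicit
    ``resident_frequencies`` are given; the initial state then scales the
    resident frequencies by ``1 - invasion_fraction`` and splits the
    invasion fraction equally among invaders.
    """
    resident_labels = tuple(resident_labels)
    invader_labels = tuple(invader_labels)
    if not (0.0 < invasion_fraction < 0.5):
        raise InputError("invasion_fraction must lie in (0, 0.5)")
    if set(resident_labels) & set(invader_labels):
        raise InputError("resident and invader labels must be disjoint")
    for lbl in resident_labels + invader_labels:
        if lbl not in tensor.players:
            raise InputError(f"unknown genotype label {lbl!r}")

    if resident_frequencies is None:
        if len(resident_labels) == 1:
            resident_freqs = np.array([1.0])
        else:
            sub = restrict_tensor(tensor, resident_labels)
            pre = integrate(
                np.full(len(resident_labels), 1.0 / len(resident_labels)),
                sub, t_max=t_max, tol=tol,
            )
            resident_freqs = pre.states[-1]
    else:
        resident_freqs = np.asarray(resident_frequencies, dtype=float)
        resident_freqs = resident_freqs / resident_freqs.sum()

    x0 = np.zeros(len(tensor.players))
    for lbl, f in zip(resident_labels, resident_freqs):
        x0[tensor.players.index(lbl)] = f * (1.0 - invasion_fraction)
    for lbl in invader_labels:
        x0[tensor.players.index(lbl)] = invasion_fraction / len(invader_labels)
    return integrate(x0, tensor, t_max=t_max, tol=tol)


#: named invasion scenarios for the four-genotype (11/01/10/00) system:
#: simultaneous triple invasion of the full producer; the second step of a
#: progressive loss of prototrophy (10 and 00 invade an equilibrated 11+01
#: community); and the two partial producers invading the full producer.
INVASION_SCENARIOS = {
    "simultaneous_triple": {"residents": ("11",), "invaders": ("00", "01", "10")},
    "two_step_loss": {"residents": ("11", "01"), "invaders": ("10", "00")},
    "partial_producers": {"residents": ("11",), "invaders": ("01", "10")},
}


def run_invasion_scenario(
    tensor: PayoffTensor,
    scenario: str,
    invasion_fraction: float = 0.01,
    t_max: float = 1000.0,
    tol: float = 1e-7,
) -> Trajectory:
    """Run one of the named invasion experiments on a 4-genotype tensor."""
    if scenario not in INVASION_SCENARIOS:
        raise InputError(
            f"unknown scenario {scenario!r}; choose from {sorted(INVASION_SCENARIOS)}"
        )
    spec = INVASION_SCENARIOS[scenario]
    return invade(
        spec["residents"], spec["invaders"], invasion_fraction, tensor,
        t_max=t_max, tol=tol,
    )


def selection_coefficient(tensor: PayoffTensor, freq_ratio: float) -> float:
    """Selection coefficient of the mutant in a 2-genotype game.

    With players ``(WT, MT)`` and ``freq_ratio = x_MT / x_WT``, evaluates
    ``s = (f_MT(x) - f_WT(x)) / phi(x)`` at the implied composition.
    Negative frequency dependence appears as ``s`` decreasing in the ratio
    for cross-feeding-type payoffs.
    """
    if tensor.n_strategies != 2:
        raise InputError("selection_coefficient needs a 2-genotype tensor")
    if freq_ratio <= 0:
        raise InputError("freq_ratio must be positive")
    x_mt = freq_ratio / (1.0 + freq_ratio)
    x = np.array([1.0 - x_mt, x_mt])
    f = fitness(x, tensor)
    phi = float(f @ x)
    if phi <= 0:
        raise InputError("mean fitness non-positive at the evaluation point")
    return float((f[1] - f[0]) / phi)
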