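"""Replicator dynamics: fixed points, convergence, invasions, selection."""

import numpy as np
import pytest

import fluxgames as fg
from fluxgames.dynamics import (
    INVASION_SCENARIOS,
    fitness,
    run_invasion_scenario,
)
from fluxgames.errors import InputError
from fluxgames.fixtures import prisoners_dilemma, snowdrift


def closed_form_interior(tensor):
    """Interior fixed point of a 2x2 symmetric game [[a,b],[c,d]]:
    x* = (b - d) / ((b - d) + (c - a))."""
    (l1, l2) = tensor.players
    a, b = tensor.payoff(l1, l1), tensor.payoff(l1, l2)
    c, d = tensor.payoff(l2, l1), tensor.payoff(l2, l2)
    return (b - d) / ((b - d) + (c - a))


def test_monomorphic_state_is_fixed_point(amino_tensor):
    K = amino_tensor.n_strategies
    for k in range(K):
        x = np.zeros(K)
        x[k] = 1.0
        assert np.allclose(fg.replicator_rhs(x, amino_tensor), 0.0, atol=1e-12)


def test_uniform_payoffs_neutral_everywhere(rng):
    t = fg.bimatrix([[2.0, 2.0], [2.0, 2.0]])
    for _ in range(5):
        x = rng.dirichlet([1, 1])
        assert np.allclose(fg.replicator_rhs(x, t), 0.0, atol=1e-12)


def test_rhs_matches_explicit_2x2_formula():
    t = snowdrift()  # [[2,1],[3,0]]
    x1 = 0.3
    x = np.array([x1, 1 - x1])
    f1 = 2 * x1 + 1 * (1 - x1)
    f2 = 3 * x1 + 0 * (1 - x1)
    phi = f1 * x1 + f2 * (1 - x1)
    expected = np.array([(f1 - phi) * x1, (f2 - phi) * (1 - x1)])
    assert np.allclose(fg.replicator_rhs(x, t), expected, atol=1e-12)


def test_rhs_sums_to_zero_and_higher_order_terms(amino_system, rng):
    t2 = amino_system.build_tensor(order=2)
    t3 = amino_system.engine().build_payoff_tensor(list(amino_system.genotypes), order=3)
    for _ in range(5):
        x = rng.dirichlet(np.ones(4))
        dx = fg.replicator_rhs(x, [t2, t3])
        assert abs(dx.sum()) < 1e-12
        # extended fitness = pairwise term + quadratic term
        f = fitness(x, [t2, t3])
        f2 = t2.to_array() @ x
        f3 = (t3.to_array() @ x) @ x
        assert np.allclose(f, f2 + f3, atol=1e-12)


def test_snowdrift_reaches_closed_form_interior_equilibrium():
    t = snowdrift()
    x_star = closed_form_interior(t)  # 0.5
    traj = fg.integrate([0.9, 0.1], t, tol=1e-9)
    assert traj.converged
    assert traj.final_state["C"] == pytest.approx(x_star, abs=1e-6)
    assert np.max(np.abs(traj.states.sum(axis=1) - 1.0)) <= 1e-8


def test_prisoners_dilemma_defector_fixation():
    traj = fg.integrate([0.99, 0.01], prisoners_dilemma())
    assert traj.converged
    assert traj.final_state["D"] == pytest.approx(1.0, abs=1e-4)


def test_vertex_start_stays_at_vertex(amino_tensor):
    x0 = np.array([0.0, 1.0, 0.0, 0.0])
    traj = fg.integrate(x0, amino_tensor, t_max=50.0)
    assert np.allclose(traj.states[-1], x0, atol=1e-9)


def test_non_convergence_reported():
    # matching-pennies-style rock-paper-scissors cycles forever
    rps = fg.bimatrix(
        [[0.0, -1.0, 1.0], [1.0, 0.0, -1.0], [-1.0, 1.0, 0.0]],
        labels=("R", "P", "S"),
    )
    traj = fg.integrate([0.5, 0.3, 0.2], rps, t_max=30.0)
    assert traj.equilibrium == "not converged"


def test_invasions_from_both_directions_agree():
    t = snowdrift()
    a = fg.invade(["C"], ["D"], 0.01, t, t_max=5000).final_state["C"]
    b = fg.invade(["D"], ["C"], 0.01, t, t_max=5000).final_state["C"]
    assert abs(a - b) <= 1e-4


def test_dominant_invader_fixates_regardless_of_fraction():
    t = prisoners_dilemma()
    for frac in (0.001, 0.05, 0.2):
        traj = fg.invade(["C"], ["D"], frac, t)
        assert traj.final_state["D"] == pytest.approx(1.0, abs=1e-4)


def test_neutral_game_keeps_initial_frequencies():
    t = fg.bimatrix([[1.0, 1.0], [1.0, 1.0]])
    traj = fg.invade(["C"], ["D"], 0.05, t, t_max=20.0)
    assert traj.final_state["D"] == pytest.approx(0.05, abs=1e-9)


def test_strict_nash_vertices_resist_small_invasions(amino_tensor):
    """Strict symmetric Nash equilibria are locally stable monomorphic
    states: a 1e-3 invasion decays back."""
    nash = fg.find_nash_ilp(amino_tensor)
    labels = amino_tensor.players
    for profile in nash.equilibria:
        if len(set(profile)) != 1:
            continue
        res = profile[0]
        # strictness check
        stay = amino_tensor.payoff(res, res)
        if any(
            amino_tensor.payoff(alt, res) >= stay - 1e-9
            for alt in labels
            if alt != res
        ):
            continue
        invaders = [l for l in labels if l != res]
        traj = fg.invade([res], invaders, 1e-3, amino_tensor, t_max=500)
        assert traj.final_state[res] == pytest.approx(1.0, abs=1e-3)


def test_invasion_scenarios_run_and_conserve_simplex(amino_tensor):
    for name in INVASION_SCENARIOS:
        traj = run_invasion_scenario(amino_tensor, name, t_max=2000)
        assert np.max(np.abs(traj.states.sum(axis=1) - 1.0)) <= 1e-8
        assert np.min(traj.states) >= -1e-12


def test_invasion_input_validation(amino_tensor):
    with pytest.raises(InputError):
        fg.invade(["11"], ["nope"], 0.01, amino_tensor)
    with pytest.raises(InputError):
        fg.invade(["11"], ["01"], 0.7, amino_tensor)


# --------------------------------------------------------------------- #
# selection coefficients
# --------------------------------------------------------------------- #
def test_selection_coefficient_zero_for_equal_payoffs():
    t = fg.bimatrix([[2.0, 2.0], [2.0, 2.0]], labels=("WT", "MT"))
    for r in (0.1, 1.0, 10.0):
        assert fg.selection_coefficient(t, r) == 0.0


def test_selection_coefficient_rare_mutant_limit():
    t = fg.bimatrix([[2.0, 1.0], [3.0, 0.5]], labels=("WT", "MT"))
    limit = (3.0 - 2.0) / 2.0  # (a_MT,WT - a_WT,WT) / a_WT,WT
    s = fg.selection_coefficient(t, 1e-9)
    assert s == pytest.approx(limit, abs=1e-6)


def test_selection_coefficient_crosses_zero_at_interior_equilibrium():
    t = snowdrift()
    x_star = closed_form_interior(t)
    ratio_star = (1 - x_star) / x_star  # MT/WT with WT = first label
    assert fg.selection_coefficient(t, ratio_star) == pytest.approx(0.0, abs=1e-12)
    assert fg.selection_coefficient(t, ratio_star / 2) > 0
    assert fg.selection_coefficient(t, ratio_star * 2) < 0


def test_selection_coefficient_errors_on_nonviable_reference():
    t = fg.bimatrix([[-0.05, -0.05], [-0.05, -0.05]], labels=("WT", "MT"))
    with pytest.raises(InputError):
        fg.selection_coefficient(t, 1.0)
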