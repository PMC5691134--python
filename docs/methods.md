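# Methods

## Model and assumptions

The package couples three layers:

**Constraint-based fitness estimates.** A metabolic network is a
stoichiometric matrix S (metabolites × reactions) with flux bounds; flux
balance analysis (FBA) maximizes the flux of a biomass pseudo-reaction
subject to steady-state mass balance S·v = 0 and the bounds. The optimal
biomass flux (h⁻¹) of a genotype's constrained problem is its game payoff.
A genotype adds three constraint families: deleted reactions are fixed to
zero flux; leaky metabolites carry a forced exchange lower bound e_i
(mmol·gDW⁻¹·h⁻¹); metabolites supplied by partners or the medium relax the
exchange lower bound to −u_i. The two FBA problems of an interacting pair
are solved independently, each assuming the availability the other
*declares* through its leak parameters — there is no shared mass balance, no
concentration dynamics, and no feedback from partner viability onto supply.
This keeps a K-genotype, n-player game at K^n small LPs and is the central
approximation: a dead partner still "supplies" its declared leak within a
single payoff evaluation, which is why equilibria are additionally annotated
as viable/non-viable (a profile is viable only if every member grows).

**Exchange-rule choice.** When a metabolite is both leaked by the focal
genotype and supplied by partners, two readings of the constraints exist and
both are implemented on the payoff engine (`exchange_rule`):

* `net` (default): the exchange flux must satisfy v_EX ≥ e_i regardless of
  supply — a forced *net* export. Partner supply of a metabolite you
  yourself leak is unusable. This is the natural reading for genetically
  forced amino-acid leakage and is used by the two-amino-acid system.
* `gross`: v_EX ≥ e_i − u_i — forced *gross* secretion with recapture of the
  shared pool allowed up to what partners put in. This is the right physics
  when leakage is structural, as in the sucrose system, where a fixed
  fraction of the hydrolysis product enters a common extracellular pool from
  which every cell, including the producer, feeds. Under the `net` rule a
  producer facing a producer would gain nothing from the pool, forcing
  a(WT,WT) = a(WT,MT) and collapsing the cheater-invasion boundary onto the
  producer-viability boundary, which erases the snowdrift band entirely.

**Death rate and viability.** An infeasible genotype problem — or a feasible
one with biomass below the viability threshold (default 1e-6 h⁻¹) — earns
the death rate, a configurable negative constant (default −0.05 h⁻¹). Its
magnitude only scales how fast dead genotypes decay under the replicator
dynamics; it never changes Nash membership among viable profiles, because
all comparisons involving dead strategies are ties at the same constant or
dominated by any viable payoff.

**Nash enumeration.** For every strategy profile a binary indicator w is
constrained by, per player m, a_m ≥ M_m·w + LB_m·(1 − w), where M_m is the
best unilateral deviation of player m and LB_m is set automatically to
(min payoff − 1 − |min payoff|), strictly below every payoff so the
constraint is slack at w = 0. Maximizing Σw over binaries (HiGHS
branch-and-bound, absolute gap 0) yields all pure-strategy equilibria in one
solve. The all-zero assignment is always feasible, so an empty equilibrium
set appears as optimum z = 0 rather than infeasibility. Equilibria are weak:
Eq-style ≥ comparisons admit ties, and the brute-force oracle uses the same
weak inequality with a 1e-9 tie tolerance. The ILP and the oracle are
cross-checked on hundreds of random 2–4-player games in the test suite.

**Game classification.** Two-strategy producer/non-producer games are
labelled from payoff orderings: snowdrift when each strategy is the best
reply to the other (a_DC > a_CC and a_CD > a_DD), mutually beneficial when
(C,C) is an equilibrium and (D,D) is not, prisoner's dilemma when defection
is the best reply to everything yet mutual production pays more
(a_DC > a_CC, a_DD ≥ a_CD, a_CC > a_DD), producer dominance when only the
producer is ever viable, non-viable when no profile grows, and `other` for
the remaining orderings. For non-degenerate payoffs these conditions are
exactly the Nash-set characterizations; stating them on orderings keeps the
labels stable where dead strategies tie exactly at the death rate (in a
collapse region both (C,D) and (D,D) are weak equilibria at the same
constant, yet the cell is a dilemma, not an anti-coordination game).

**Replicator dynamics.** dx_k/dt = (f_k(x) − φ(x))·x_k with f_k summing one
term per interaction order supplied (pairwise A·x; three-player x'·A_k·x;
…) and φ = f·x. Integration uses adaptive RK45 with rtol 1e-8 / atol 1e-10.
The integrated vector field is evaluated on the clipped, renormalized state:
off the simplex the raw field is exponentially unstable whenever φ < 0
(death-rate payoffs), and the projection keeps Σ dx/dt = 0 exactly;
trajectories are renormalized only within 1e-8. Convergence is declared when
‖dx/dt‖∞ falls below the tolerance (default 1e-7, a terminal integrator
event); otherwise the trajectory reports "not converged". Note that a vertex
dominated by a dying community (everyone at the death rate) is a legitimate
fixed point: frequencies are relative, so "the least-dead genotype takes
over" can be the outcome of a collapse.

**Invasions and selection coefficients.** An invasion experiment first
equilibrates the residents among themselves (sub-game replicator run from a
uniform start), then rescales residents by (1 − invasion fraction; default
0.01) and splits the fraction equally among invaders. Three named scenarios
cover the canonical paths toward cross-feeding: a simultaneous triple
invasion of the full producer; 10 and 00 invading an equilibrated 11+01
community (the second step of progressive prototrophy loss); and the two
partial producers invading the full producer. The selection coefficient of a
mutant at frequency ratio r = x_MT/x_WT is s = (f_MT − f_WT)/φ at the
implied composition — one of several conventions in use; it is exposed as a
function so alternatives can be evaluated directly from the tensor.

## Synthetic study systems

The fixtures are deliberately small (4–7 metabolites, single carbon source,
integer stoichiometry) so every payoff has a hand-checkable closed form; the
test suite freezes those closed-form values.

**Sucrose public good.** Sucrose (uptake bound 10) is hydrolyzed at an ATP
cost x into two hexoses, a fraction e of which enters a shared pool
(capture efficiency 1 − e); the producer's sucrose uptake is fixed at its
bound, making the leak unavoidable rather than strategic. ATP comes from an
efficient, capacity-limited route (3 ATP/hexose, cap 5) or an unbounded
overflow route (1 ATP/hexose) — the standard overflow-metabolism motif,
included because a concave growth return on hexose is what separates the
cheater-invasion boundary from the producer-viability boundary; with a
purely linear network the snowdrift band would be a measure-zero line.
Closed forms on the default parameters: a(WT,WT) = 15 − 5x,
a(MT,WT) = 15e (for e ≤ 1), a(WT,MT) = 15 − 15e − 2.5x or 15 − 10e − 5x
depending on the active catabolic regime. The supplemented-medium condition
adds 2 flux units of free hexose for every player; on the default cost grid
x ∈ [0, 2.4] this weakly enlarges the prisoner's-dilemma region (the
boundaries 2e + x ≥ 3 and e > 1 − x/3 relax to 2e + x ≥ 2.9 and
e > 0.967 − x/3, as the closed forms show), chosen at that size because a
large supplement would let the cheater pair outgrow cooperation entirely and
re-label high-cost dilemma cells as mere dominance.

**Two amino acids.** Carbon → precursor → {A, B} at ATP costs cost_A,
cost_B; biomass consumes precursor + A + B + ATP. Genotypes 11/01/10/00
delete the corresponding synthesis genes; each genotype leaks what it can
synthesize, at a per-amino-acid rate expressed as a percentage of the full
producer's maximum sustainable leak e_max (computed by bisection with the
other leak at zero, matching how leakiness axes are usually displayed).
Pleiotropy routes A synthesis through an intracellular, non-exchangeable
intermediate of the B pathway, so the B-pathway mutant (10) cannot make or
leak A even when fed B — cross-feeding is structurally impossible. Epistasis
makes both syntheses co-produce an essential biomass side-compound with an
expensive salvage route (6 ATP), so the double mutant facing the producer is
*less* fit than a single mutant, which removes [00, 11] from the equilibrium
set in part of the sustainable region. With biomass needing one unit of each
amino acid per unit growth, the toy's amino-acid requirements are far larger
relative to growth than in a genome-scale model; leak costs are therefore
steep, regions are compressed, and the landscape patterns should be read
qualitatively (region existence, adjacency, monotonicity), not as flux-level
predictions for any real organism.

**Random viable networks.** A linear uptake→chain→biomass backbone
guarantees feasibility with optimal biomass equal to the uptake bound; extra
random reactions consume one or two metabolites and produce one, so total
mass never increases and the LP stays bounded. Used for property tests
(oracle: an independently assembled dense LP).

## Numerical choices

* LP/MIP backend: HiGHS through scipy (`linprog`/`milp`); LP feasibility at
  solver defaults (~1e-9), post-hoc mass-balance checks at 1e-6.
* Payoffs are rounded to 1e-9 before entering tensors so analytic ties
  (notably at the death-rate constant) compare exactly.
* Bisection for the maximum sustainable leak: bracket grown by doubling from
  the model's total uptake capacity × largest stoichiometric coefficient;
  default absolute tolerance 1e-4 of the initial bracket. The pre-condition
  is a viable genotype at zero leak; a metabolite the genotype cannot export
  returns 0.
* Default grids: 21 levels per leakiness axis (0–100 % in 5 % steps, 441
  cells); the shipped analyses and the acceptance script use 11 × 11
  leakiness grids and a 13 × 11 cost × capture grid, which resolve every
  region while keeping a full multi-coupling run under a minute.
* Landscape scans are deterministic: no randomness anywhere in the pipeline;
  rerunning a config reproduces byte-identical TSV/JSON artifacts.

## Known limitations

* Fixed leak rates: no eco-evolutionary feedback, no population sizes, no
  dynamic medium — the replicator equation tracks frequencies only.
* Pure-strategy equilibria only; mixed strategies and refinements are out of
  scope.
* Gene→reaction mapping is a plain many-to-many union (a reaction is removed
  if any deleted gene maps to it); boolean gene-protein-reaction logic is
  not evaluated.
* SBML import is best-effort (species, reactions, FBC or ±1000 default
  bounds, objective → biomass); the package's own JSON schema is the
  canonical format.
* Passing the fixture-based tests demonstrates the machinery and the
  qualitative mechanisms (public-good dilemmas, cross-feeding regions,
  pleiotropy/epistasis effects), not quantitative agreement with any
  genome-scale reconstruction.
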