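# fluxgames

Genome-driven evolutionary game theory for microbial communities: estimate
the fitness of interacting genotypes with constraint-based metabolic models,
enumerate every pure-strategy Nash equilibrium of the resulting game with an
exact integer linear program, and simulate replicator dynamics to find which
equilibria are evolutionarily stable.

## The problem

Microbes leak costly metabolites — amino acids, hydrolysis products of
public-good enzymes — that neighbours can exploit. A mutant that stops
producing such a "Black Queen" function saves the cost and may outcompete
producers, which can end in stable coexistence, unidirectional dependency,
obligate reciprocal cross-feeding, or community collapse. Which outcome wins
depends on the underlying biochemistry: biosynthetic costs, pathway
pleiotropy, epistasis between deletions, and how much of the product leaks.
`fluxgames` turns those mechanistic details into game-theoretic predictions
for systems/evolutionary biologists studying metabolic interdependencies and
for designers of synthetic consortia.

## The method

1. **Payoffs from FBA.** For each genotype *k* facing opponents *k′, …* we
   solve a flux balance analysis LP

   maximize v_biomass subject to Σ_j s_ij v_j = 0 (∀ i), LB_j ≤ v_j ≤ UB_j,

   extended with genotype constraints: v_j = 0 for deleted reactions
   (j ∈ J^mutation), forced secretion v_EX_i ≥ e_i for leaky metabolites
   (i ∈ I^leaky), and uptake allowances v_EX_i ≥ −u_i for metabolites the
   partners supply (u_i = Σ partners' e_i). The optimal biomass flux is the
   payoff a_kk′…; an infeasible or sub-viability problem yields a negative
   death rate. All K^n ordered profiles form the payoff tensor.

2. **Nash enumeration by ILP.** One binary w per profile, with the big-M
   constraint a¹_pq ≥ (max_p′ a¹_p′q)·w_pq + LB₁(1 − w_pq) for player 1 (and
   analogues for every player); maximizing Σ w flags **all** pure-strategy
   Nash equilibria in a single exact MIP solve (HiGHS branch-and-bound,
   zero gap), cross-checked against brute-force deviation enumeration.

3. **Replicator dynamics.** dx_k/dt = (f_k(x) − φ(x)) x_k with
   f_k = Σ a_kk′ x_k′ (+ higher-order terms) and φ = Σ f_k x_k, integrated
   adaptively; in silico invasion experiments start a low-frequency genotype
   in an equilibrated resident community.

4. **Landscapes.** 2-D parameter scans (leakiness × leakiness, or hydrolysis
   cost × capture efficiency) classify each cell's game
   (prisoner's dilemma / snowdrift / mutually beneficial / …) and delineate
   the sustainable-leakiness and cross-feeding-only regions.

No external data are needed: the `fixtures` module generates small
stoichiometric systems that structurally emulate the studied biology — a
sucrose/invertase public good with tunable ATP cost and capture efficiency,
and a two-amino-acid biosynthesis system with the genotypes 11/01/10/00 and
optional pleiotropic or epistatic pathway coupling — plus random viable
networks for property testing. SBML (FBC) import is supported for real
models.

## Worked example

```python
import fluxgames as fg

system = fg.make_sucrose_fixture(atp_cost_x=1.0, public_fraction=0.6)
tensor = system.build_tensor()
for focal in tensor.players:
    print(focal, [round(tensor.payoff(focal, opp), 4) for opp in tensor.players])
nash = fg.find_nash_ilp(tensor)
print(fg.classify_game(nash, tensor, "WT", "MT").label, nash.equilibria)
```

prints

```
WT [10.0, 3.5]
MT [9.0, -0.05]
mutually_beneficial (('WT', 'WT'),)
```

Producers (WT) earn biomass flux 10.0 h⁻¹ among themselves and still 3.5
facing the cheater; the cheater (MT) reaches only 9.0 against producers and
dies alone (death rate −0.05), so at this cost/leak combination mutual
production is the unique equilibrium. Raising the hydrolysis cost or the
leaked fraction moves the same system through snowdrift coexistence into a
prisoner's dilemma — run `python examples/04_landscape_scan.py` to print the
full phase diagram, and see the other `examples/` scripts for Nash
enumeration, invasion experiments and payoff construction.

## Command line

A thin CLI mirrors the pipeline stages:

```bash
fluxgames fixture sucrose -o demo/
fluxgames payoff demo/model.json demo/genotypes.json -o demo/payoffs.tsv --exchange-rule gross
fluxgames nash --payoffs demo/payoffs.tsv
fluxgames scan --fixture two_amino_acid --axis1 leakiness_A:0:100:11 --axis2 leakiness_B:0:100:11 -o demo/landscape.tsv
fluxgames run config.json   # full pipeline from a config file
```
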