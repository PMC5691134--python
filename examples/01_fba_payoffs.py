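"""Estimate game payoffs with flux balance analysis.

Builds the toy sucrose public-good system (producer WT hydrolyzes sucrose at
an ATP cost and loses a fraction of the hexose product to a shared pool;
non-producer MT can only eat from that pool) and prints the 2x2 payoff
matrix.  Payoffs are optimal biomass fluxes (h^-1); a dead strain gets the
death rate -0.05.
"""

import fluxgames as fg

system = fg.make_sucrose_fixture(atp_cost_x=1.0, public_fraction=0.6)

wt_alone = fg.genotype_fba(system.model, system.genotype("WT"), exchange_rule="gross")
print(f"WT biomass flux alone: {wt_alone.biomass_flux:.4f} h^-1")

tensor = system.build_tensor()
print("\npayoff matrix a(focal, opponent):")
for focal in tensor.players:
    row = "  ".join(f"{tensor.payoff(focal, opp):8.4f}" for opp in tensor.players)
    print(f"  {focal}:  {row}")
print(
    "\nThe producer keeps a positive payoff facing the cheater, while the\n"
    "cheater does better against producers than producers do among\n"
    "themselves: the raw material of a social dilemma."
)
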