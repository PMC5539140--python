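"""Flux balance analysis on two small fixtures.

Builds the linear-chain and redox-coupled toy networks and maximizes their
biomass flux.  The chain's optimum equals its uptake bound (conservation
along a single path); the redox toy grows at 7.5 because the NADH balance
forces 5 flux units through the fermentative sink.
"""

from tagknock import make_linear_chain, make_redox_coupled_toy, solve_fba

chain, chain_truth = make_linear_chain(uptake_limit=10.0)
sol = solve_fba(chain)
print(f"linear chain: max growth = {sol.objective_value:.6f} (expected {chain_truth.max_growth})")

redox, redox_truth = make_redox_coupled_toy()
sol = solve_fba(redox)
print(f"redox toy:    max growth = {sol.objective_value:.6f} (expected {redox_truth.max_growth})")
print(f"  fermentation flux FERM_E = {sol.fluxes['FERM_E']:.6f}  (NADH sink at the optimum)")
print(f"  TAG branch flux  FERM_T = {sol.fluxes['FERM_T']:.6f}  (idle in the wild type)")
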