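"""The stoichiometry-only baselines next to the enzyme-constrained optimum.

On a single-enzyme chain the crowding baseline (one linear cost per unit
flux, a_j = MW/(kcat*C)) coincides with the enzyme-capacity model, while
plain FBA needs an arbitrary uptake bound and predicts yield, not rate.
"""

from momentfba import (
    CrowdingParams,
    build_moment,
    chain_toy,
    fba,
    fbawmc,
    fva,
    solve_moment,
)

toy = chain_toy(kcats=(100.0,), mws=(1.0,), C=0.27)

sol = solve_moment(build_moment(toy.model, toy.params, toy.medium))
print(f"enzyme-constrained growth: {sol.growth:.3f} 1/h  (no uptake bound needed)")

crowding = CrowdingParams.from_enzyme_params(toy.model, toy.params)
_, g_wmc = fbawmc(toy.model, toy.medium, crowding)
print(f"crowding baseline growth:  {g_wmc:.3f} 1/h  (same kcat/MW tables)")

res = fba(toy.model, toy.medium, uptake_bound=10.0)
print(f"FBA at uptake 10:          {res.objective:.3f} 1/h, "
      f"yield {res.biomass_yield:.2f} biomass per substrate")

ranges, unique = fva(toy.model, toy.medium, objective_fraction=1.0, uptake_bound=10.0)
print(f"FVA uniquely determined reactions at optimum: {sorted(unique)}")
# A linear chain admits exactly one flux pattern at the optimum, so every
# reaction is uniquely determined; parallel routes would show wide ranges.
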