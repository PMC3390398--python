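"""Predict growth from enzyme kinetics alone — no uptake measurement.

A two-step pathway (uptake -> R1 -> R2 -> biomass) where each step is
catalyzed by one enzyme.  The only growth-limiting resource is the total
enzyme mass budget C: faster (higher kcat) or lighter (lower MW) enzymes
buy more flux per gram.  The optimum has the closed form
C / sum_j(MW_j / kcat_j), which the LP reproduces.
"""

from momentfba import build_moment, chain_toy, solve_moment

toy = chain_toy(kcats=(100.0, 50.0), mws=(1.0, 1.0), C=0.27)
sol = solve_moment(build_moment(toy.model, toy.params, toy.medium))

print(f"status:            {sol.status}")
print(f"growth rate:       {sol.growth:.4f} 1/h (closed form {toy.analytic_optimum:.4f})")
print(f"enzyme mass used:  {sol.mass_used:.4f} of C = {toy.params.capacity_C} g/gDW")
for gene, conc in sorted(sol.g.items()):
    print(f"  {gene}: {conc:.4f} mmol/gDW")
print("binding constraints:", ", ".join(sol.binding))
# The mass budget is spent entirely (the mass row is binding): the slower
# enzyme g2 needs twice the concentration per unit flux, so it receives
# twice the mass of g1.
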