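"""Fitting a genome-scale flux distribution to sparse measurements.

Measured fluxes rarely satisfy mass balance exactly.  The quadratic
program projects them onto the steady-state flux cone: it minimizes the
squared distance to the measurements over the measured reactions while
unmeasured fluxes absorb whatever mass balance requires.
"""

from momentfba import chain_toy, fit_fluxes_qp

toy = chain_toy(kcats=(100.0,), mws=(1.0,), C=0.5)
# the chain forces EX_src = R1 = BM; measurements (1, 3) are inconsistent
res = fit_fluxes_qp(toy.model, {"EX_src": 1.0, "R1": 3.0}, toy.medium)

print("fitted fluxes (mmol/gDW/h):")
for rid, v in sorted(res.v.items()):
    print(f"  {rid}: {v:.3f}")
print(f"sum of squared residuals: {res.sse:.3f}")
# The feasible compromise puts both fluxes at 2: (2-1)^2 + (2-3)^2 = 2,
# the least-squares projection of (1, 3) onto the line v1 = v2.
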