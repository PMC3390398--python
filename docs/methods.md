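# Methods

## Model

The solver couples a standard constraint-based metabolic model to an
enzyme-allocation problem. Over flux variables `v_j` (mmol/gDW/h),
gene-product concentrations `g_i` (mmol/gDW) and auxiliary complex
concentrations `u`, it solves the LP

```
max  v_biomass
s.t. S·v = 0
     v_lb ≤ v ≤ v_ub
     v_j ≤ kcat_j · h_j(g, u)        for every reaction with a GPR rule
     u ≤ h_child(g, u)               for every AND node, each child
     Σ_i MW_i · g_i ≤ C
     g, u ≥ 0
```

where `h_j` is the capacity expression compiled from reaction *j*'s
Boolean gene-reaction (GPR) rule: a gene leaf contributes its shared
variable `g_i`; an OR node (isozymes) contributes the sum of its
children's expressions; an AND node (complex) contributes a fresh
auxiliary variable `u` constrained below each child's expression
(the scarcest subunit limits the complex). Nesting is handled by
recursion, so arbitrarily deep rules stay within a single LP.

Assumptions inherited from the formulation, and their consequences:

- **Full saturation.** `v = kcat·g` treats every enzyme as operating at
  its maximal rate; no Km/saturation terms, no metabolite
  concentrations, no thermodynamic (ΔG) constraints. Predictions are
  upper envelopes of what partially saturated enzymes could do.
- **Shared pools for multi-functional enzymes.** A gene used by several
  reactions has one concentration variable, counted once in the mass
  row, but each reaction's capacity row may independently consume the
  full pool. This is deliberately kept literal (it is the stated
  formulation) and undercounts the true cost of moonlighting enzymes.
  Likewise a gene repeated in several OR branches of one rule is
  summed per branch (a warning is logged).
- **1:1 complex stoichiometry, massless auxiliaries.** Subunit
  stoichiometry inside complexes is not modeled; auxiliary variables
  carry no molecular weight (the mass row sums over genes only).
- **Uncapacitated spontaneous/exchange reactions.** Reactions without a
  GPR get no capacity row; uptake limitation emerges from transporter
  GPRs, not from ad hoc exchange bounds.

Reversible reactions are split into nonnegative forward/backward
components; both directions are bounded by the same capacity expression
and kcat (a direction-specific backward kcat is honored when supplied).
This is a modeling choice — the capacity relation is meaningless for
signed flux — and the minimal one consistent with one kcat per reaction.

## Parameters and units

| parameter | unit | default | notes |
|---|---|---|---|
| kcat | 1/h internally; 1/s in files | — | per reaction; per-(reaction, gene) overrides for isozymes |
| MW | g/mmol internally; Da in files | — | per gene, computable from protein FASTA |
| C (enzyme capacity) | g enzyme/gDW | 0.27 | fitted value; 0.56 = total protein mass fraction as ceiling |
| fluxes | mmol/gDW/h | — | growth = biomass flux, 1/h |

With these units `MW_i·g_i` is directly a mass fraction, so the
capacity row needs no conversion factors. `C` only sets the overall
scale: the optimum is exactly linear in `C` (growth(αC) = α·growth(C)),
which is both a tested invariant and the basis of the closed-form
capacity fit `C* = C0 · Σ p·m / Σ p²` against measured rates.

kcat assembly provenance order: mutant records dropped; own-organism
records → median; other-species records → mean of raw records (not of
per-species medians — the finer-grained convention is unspecified in
the source data, so the simpler one is used and stated here);
remaining reactions → median over all resolved values. Duplicated
measurements are kept (no deduplication before the median).
Protein MW uses average-isotope residue masses plus one water
(bulk mass budgeting, not monoisotopic); `X` gets the mean residue mass.

## Numerical choices

- LPs: `scipy.optimize.linprog` (HiGHS), feasibility/optimality
  tolerances 1e-9. Solutions are validated post-hoc (mass-balance
  residual and capacity slack ≤ 1e-6) before being returned.
- QPs (flux fitting; the ε-scan for max ATP per Σv²): SLSQP from a
  feasible interior start; both objectives are strictly convex
  diagonal quadratics, where SLSQP on problems of this size converges
  to ~1e-8. The ε-scan solves `max ε·v_ATP − Σv²` on a grid over
  [0.5, 1.5] (default 10000 points; the grid is configurable and tests
  use ~100) and selects by the true ratio `v_ATP/Σv²`; the uptake is
  fixed because the ratio is scale-degenerate.
- Degenerate optima in `g`: growth is unique but the allocation often
  is not (equal-weight isozymes). `solve_moment(parsimonious=True)`
  re-solves at fixed optimal growth minimizing `Σ MW·g`, giving a
  canonical allocation; it is the default for differential-enzyme
  predictions and off elsewhere. Variability that survives the growth
  constraint is quantified by `moment_fva` (uniqueness flag at range
  width ≤ 1e-6).
- FVA conventions: the plain-FBA `fva` constrains the objective to
  ≥ fraction×optimum (so fraction 0 yields the raw mass-balance cone);
  `moment_fva` fixes growth with an equality, matching its role of
  probing alternate optima at a given rate.
- Infeasibility diagnosis: on an infeasible solve the problem is
  re-solved without capacity and mass rows to report which constraint
  class (enzyme capacity vs stoichiometry/bounds) is responsible.
  An unbounded status signals a biomass route with no capacity row and
  no uptake bound (e.g. a GPR-less cycle).
- The brute-force oracle enumerates basic feasible points (all active
  sets of the inequality system, equalities always active) in float64
  with a 1e-7 feasibility tolerance; infinite bounds are replaced by a
  ±1e6 box, and an optimum attained only on that box is classified
  unbounded. It refuses problems beyond ~3·10⁵ candidate bases and
  exists purely as an independent check on the solver path.
- Medium semantics: an exchange reaction's uptake direction is the one
  producing its metabolite; closed exchanges have that direction
  clamped to zero while secretion stays open.

## What the synthetic fixtures do and do not show

The toy generator produces five topologies (chain, isozyme pair,
two-subunit complex, branched routes, mixed nested rule) whose optima
have closed forms — chain `C/Σ(MW/kcat)`, isozymes `kcat·C/min MW`,
complex `kcat·C/Σ MW`, branched `C·max(kcat/MW)`, mixed
`kcat·C·max(1/(MW_a+MW_b), 1/MW_c)` — with kcat log-uniform in
[10, 1000] 1/h, MW uniform in [0.5, 5] g/mmol and C uniform in
[0.1, 1] g/gDW for the randomized suites. These exercise every
compilation rule, the scaling/monotonicity/dominance algebra, and
solver-vs-oracle agreement exactly.

They are not genome-scale: no internal cycles, no cofactor coupling,
no competition between hundreds of pathways, and kcat/MW magnitudes
chosen for conditioning rather than biochemical realism. Passing tests
therefore certify the optimization machinery and the statistics, not
predictive accuracy on a real network — that requires an external
curated model and measured datasets, consumed through the same I/O
surface (SBML/JSON models, TSV tables).

Randomized suite sizes in the shipped tests and the acceptance script
(50 toys for scaling, 25 for monotonicity, 12 for oracle agreement,
1000-shuffle nulls) keep the full run in the tens of seconds while
leaving the probability of an undetected systematic violation
negligible — every toy in a suite must satisfy each property to 1e-6
relative or better.

## Known limitations

- The solver is dense-matrix over the toy scale; genome-scale models
  solve fine through HiGHS but the LP assembly makes no effort at
  sparsity beyond scipy's own.
- No sampling over missing crowding parameters in the FBAwMC-style
  baseline; its coefficients come deterministically from the heaviest
  catalyzing gene, `a_j = MW/(kcat_j·C)`.
- Differential-enzyme scores are defined only for genes expressed in
  both conditions; genes at the pseudo-floor are reported in a separate
  undefined set rather than imputed.
- The exchange-direction convention assumes each exchange reaction
  touches exactly one metabolite (validated on load).
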