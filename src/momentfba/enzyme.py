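"""Enzyme-capacity-constrained flux balance analysis (MOMENT).

The method augments FBA with a vector of enzyme (gene-product)
concentrations ``g`` (mmol/gDW) and couples each catalyzed flux to the
concentration of its enzyme through the reaction's turnover number:

* single enzyme i:            v_j <= kcat_j * g_i
* isozymes a OR b:            v_j <= kcat_j * (g_a + g_b)
* complex a AND b:            v_j <= kcat_j * u,  u <= g_a, u <= g_b

with nested rules compiled recursively through fresh auxiliary variables,
so the whole Boolean gene-reaction mapping stays inside one linear
program.  A single solvent-capacity row bounds the total enzyme mass:

    sum_i MW_i * g_i <= C        (g enzyme per gDW)

Each gene has exactly one concentration variable shared across every
reaction it catalyzes (multi-functional enzymes); the objective is
maximal flux through the biomass reaction, i.e. maximal growth rate.

Reversible reactions are split into nonnegative forward/backward
components, each bounded by the same capacity expression (a
direction-specific backward kcat is honored when provided).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import SolverError, ValidationError
from .gpr import AND, GENE, OR, GPRNode
from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LinearProgram
from .model import Medium, MetabolicModel, Reaction

log = logging.getLogger(__name__)

INF = math.inf

#: total enzyme mass fraction fitted against measured growth rates (g/gDW)
DEFAULT_CAPACITY = 0.27
#: total cellular protein mass fraction (g/gDW), the physiological ceiling
TOTAL_PROTEIN_CAPACITY = 0.56

MEASURED_SELF = "measured_self"
OTHER_SPECIES_MEAN = "other_species_mean"
GLOBAL_MEDIAN_FILL = "global_median_fill"


@dataclass
class EnzymeParams:
    """Kinetic parameters feeding the capacity constraints.

    ``kcat`` maps reaction id -> turnover number (1/h); ``kcat_backward``
    optionally overrides the reverse direction.  ``isozyme_kcat`` maps
    (reaction id, gene id) -> kcat for per-isozyme rates on OR leaves.
    ``mw`` maps gene id -> molecular weight (g/mmol).  ``capacity_C`` is
    the total enzyme mass fraction (g/gDW).  Reactions in
    ``uncapacitated`` carry no capacity row even if they have a GPR.
    """

    kcat: dict[str, float] = field(default_factory=dict)
    mw: dict[str, float] = field(default_factory=dict)
    capacity_C: float = DEFAULT_CAPACITY
    provenance: dict[str, str] = field(default_factory=dict)
    kcat_backward: dict[str, float] = field(default_factory=dict)
    isozyme_kcat: dict[tuple[str, str], float] = field(default_factory=dict)
    uncapacitated: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.capacity_C <= 0:
            raise ValidationError(
                f"capacity C must be > 0, got {self.capacity_C}"
            )
        if self.capacity_C > 1:
            # physically C is a mass fraction; >1 is allowed for scaling
            # experiments but flagged
            log.warning("capacity C=%g exceeds 1 g/gDW", self.capacity_C)
        for rid, k in self.kcat.items():
            if k <= 0:
                raise ValidationError(f"kcat for {rid!r} must be > 0, got {k}")
        for g, w in self.mw.items():
            if w <= 0:
                raise ValidationError(f"MW for {g!r} must be > 0, got {w}")

    def scaled(self, alpha: float) -> "EnzymeParams":
        """Copy with capacity multiplied by ``alpha``."""
        return EnzymeParams(
            kcat=dict(self.kcat),
            mw=dict(self.mw),
            capacity_C=self.capacity_C * alpha,
            provenance=dict(self.provenance),
            kcat_backward=dict(self.kcat_backward),
            isozyme_kcat=dict(self.isozyme_kcat),
            uncapacitated=set(self.uncapacitated),
        )


@dataclass
class CompiledConstraints:
    """Registry populated while compiling GPR trees into the LP."""

    lp: LinearProgram
    gene_vars: dict[str, str] = field(default_factory=dict)
    aux_vars: list[tuple[str, str]] = field(default_factory=list)  # (var, reaction)
    capacity_rows: list[str] = field(default_factory=list)
    mass_row: str | None = None

    def gene_var(self, gene: str) -> str:
        # one shared variable per distinct gene in the whole model
        if gene not in self.gene_vars:
            self.gene_vars[gene] = self.lp.add_var(f"g:{gene}", lb=0.0)
        return self.gene_vars[gene]


def compile_gpr(
    node: GPRNode,
    reaction: Reaction | str,
    registry: CompiledConstraints,
    isozyme_kcat: dict[tuple[str, str], float] | None = None,
    default_kcat: float | None = None,
) -> dict[str, float]:
    """Compile a GPR tree into a capacity-expression handle.

    Returns a linear expression (variable -> coefficient) such that the
    caller's capacity row is ``v_j <= kcat * handle``.  GENE leaves map to
    the shared gene variable; OR sums its children (isozymes pool
    capacity); AND introduces an auxiliary concentration ``u`` with
    ``u <= child`` for every child (the complex is limited by its
    scarcest subunit).  Auxiliary variables carry no mass.

    When per-isozyme kcats are supplied, OR leaf children are weighted by
    ``kcat_gene / default_kcat`` so that ``kcat * handle`` equals
    ``sum_i kcat_i * g_i``.
    """
    rid = reaction if isinstance(reaction, str) else reaction.id
    if node.kind == GENE:
        return {registry.gene_var(node.gene): 1.0}
    if node.kind == OR:
        expr: dict[str, float] = {}
        for child in node.children:
            child_expr = compile_gpr(child, rid, registry, isozyme_kcat, default_kcat)
            if isozyme_kcat and child.kind == GENE:
                key = (rid, child.gene)
                if key in isozyme_kcat:
                    if not default_kcat:
                        raise ValidationError(
                            f"per-isozyme kcat for {key} needs a reaction kcat"
                        )
                    child_expr = {
                        v: c * isozyme_kcat[key] / default_kcat
                        for v, c in child_expr.items()
                    }
            for v, c in child_expr.items():
                if v in expr:
                    log.warning(
                        "reaction %s: gene variable %s appears in several OR "
                        "branches; its capacity is counted per branch",
                        rid,
                        v,
                    )
                expr[v] = expr.get(v, 0.0) + c
        return expr
    # AND: fresh auxiliary variable bounded by every child expression
    u = registry.lp.add_var(f"u:{rid}:{len(registry.aux_vars)}", lb=0.0)
    registry.aux_vars.append((u, rid))
    for child in node.children:
        child_expr = compile_gpr(child, rid, registry, isozyme_kcat, default_kcat)
        coeffs = {u: 1.0}
        for v, c in child_expr.items():
            coeffs[v] = coeffs.get(v, 0.0) - c
        registry.lp.add_constraint(coeffs, "<=", 0.0, name=f"and:{u}:{child.render()}")
    return {u: 1.0}


@dataclass
class MomentSolution:
    """Result of one enzyme-constrained growth maximization."""

    status: str
    growth: float | None
    v: dict[str, float] = field(default_factory=dict)
    g: dict[str, float] = field(default_factory=dict)
    aux: dict[str, float] = field(default_factory=dict)
    mass_used: float | None = None
    binding: list[str] = field(default_factory=list)
    infeasibility_hint: str | None = None
    uptake: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def flux_table(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.v.items()), columns=["reaction", "flux"])

    def enzyme_table(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.g.items()), columns=["gene", "concentration"])


class MomentProblem:
    """A built (not yet solved) MOMENT linear program."""

    def __init__(self, model: MetabolicModel, params: EnzymeParams, medium: Medium):
        self.model = model
        self.params = params
        self.medium = medium
        self.lp = LinearProgram(name=f"moment:{model.id}:{medium.name}")
        self.registry = CompiledConstraints(self.lp)
        self._fwd: dict[str, str] = {}
        self._bwd: dict[str, str] = {}
        self._build()

    # -- construction -------------------------------------------------------
    def _build(self) -> None:
        model, params, medium = self.model, self.params, self.medium
        biomass = model.require_biomass()
        self._check_params()
        ex_bounds = model.medium_bounds(medium)

        for r in model.reactions:
            lb, ub = ex_bounds.get(r.id, (r.lb, r.ub))
            if lb < 0:
                # split into nonnegative forward/backward components
                self._fwd[r.id] = self.lp.add_var(f"vf:{r.id}", 0.0, max(ub, 0.0))
                self._bwd[r.id] = self.lp.add_var(f"vb:{r.id}", 0.0, -lb)
            else:
                self._fwd[r.id] = self.lp.add_var(f"vf:{r.id}", lb, ub)

        # steady-state mass balance over net fluxes
        for met in model.metabolites:
            coeffs: dict[str, float] = {}
            for r in model.reactions:
                c = r.metabolites.get(met, 0.0)
                if c:
                    coeffs[self._fwd[r.id]] = coeffs.get(self._fwd[r.id], 0.0) + c
                    if r.id in self._bwd:
                        coeffs[self._bwd[r.id]] = coeffs.get(self._bwd[r.id], 0.0) - c
            if coeffs:
                self.lp.add_constraint(coeffs, "==", 0.0, name=f"mb:{met}")

        # capacity rows from GPRs
        for r in model.reactions:
            if r.gpr is None or r.id in params.uncapacitated:
                continue
            kf = params.kcat.get(r.id)
            if kf is None:
                raise ValidationError(
                    f"reaction {r.id!r} has a GPR but no kcat (after fill rules)"
                )
            handle = compile_gpr(
                r.gpr, r, self.registry, params.isozyme_kcat or None, kf
            )
            kb = params.kcat_backward.get(r.id, kf)
            for var, k, tag in ((self._fwd.get(r.id), kf, "fwd"),
                                (self._bwd.get(r.id), kb, "bwd")):
                if var is None:
                    continue
                coeffs = {var: 1.0}
                for hv, hc in handle.items():
                    coeffs[hv] = coeffs.get(hv, 0.0) - k * hc
                self.registry.capacity_rows.append(
                    self.lp.add_constraint(coeffs, "<=", 0.0, name=f"cap:{r.id}:{tag}")
                )

        # solvent capacity: total enzyme mass bounded by C
        mass = {
            self.registry.gene_vars[g]: params.mw[g]
            for g in sorted(self.registry.gene_vars)
        }
        if mass:
            self.registry.mass_row = self.lp.add_constraint(
                mass, "<=", params.capacity_C, name="mass"
            )

        obj = {self._fwd[biomass]: 1.0}
        if biomass in self._bwd:
            obj[self._bwd[biomass]] = -1.0
        self.lp.set_objective(obj, maximize=True)

    def _check_params(self) -> None:
        missing_mw = sorted(
            g
            for r in self.model.reactions
            if r.gpr is not None and r.id not in self.params.uncapacitated
            for g in r.genes
            if g not in self.params.mw
        )
        if missing_mw:
            raise ValidationError(
                f"no molecular weight for GPR genes: {missing_mw}"
            )

    # -- helpers ------------------------------------------------------------
    def net_flux_expr(self, rid: str) -> dict[str, float]:
        expr = {self._fwd[rid]: 1.0}
        if rid in self._bwd:
            expr[self._bwd[rid]] = -1.0
        return expr

    def _net(self, values: dict[str, float], rid: str) -> float:
        v = values[self._fwd[rid]]
        if rid in self._bwd:
            v -= values[self._bwd[rid]]
        return v

    def _solution_from(self, values: dict[str, float], growth: float) -> MomentSolution:
        model, params = self.model, self.params
        v = {r.id: self._net(values, r.id) for r in model.reactions}
        g = {gene: values[var] for gene, var in self.registry.gene_vars.items()}
        aux = {var: values[var] for var, _ in self.registry.aux_vars}
        mass_used = sum(params.mw[gene] * conc for gene, conc in g.items())
        uptake = 0.0
        for rid in self.medium.open_exchanges:
            direction = model.uptake_direction(rid)
            uptake += max(direction * v[rid], 0.0)
        sol = MomentSolution(
            status=OPTIMAL,
            growth=growth,
            v=v,
            g=g,
            aux=aux,
            mass_used=mass_used,
            binding=self.lp.binding_constraints(values),
            uptake=uptake,
        )
        self._validate_solution(sol)
        return sol

    def _validate_solution(self, sol: MomentSolution, tol: float = 1e-6) -> None:
        resid = self.model.mass_balance_residual(sol.v)
        if resid > tol:
            raise SolverError(f"mass-balance residual {resid:g} exceeds {tol:g}")
        if sol.mass_used is not None and sol.mass_used > self.params.capacity_C + tol:
            raise SolverError(
                f"enzyme mass {sol.mass_used:g} exceeds capacity {self.params.capacity_C:g}"
            )

    def _infeasibility_hint(self) -> str:
        relaxed = LinearProgram(name=self.lp.name + ":relaxed")
        for v in self.lp.variables:
            lb, ub = self.lp.get_bounds(v)
            relaxed.add_var(v, lb, ub)
        dropped = set(self.registry.capacity_rows)
        if self.registry.mass_row:
            dropped.add(self.registry.mass_row)
        for con in self.lp.constraints:
            if con.name not in dropped and not con.name.startswith("and:"):
                relaxed.add_constraint(con.coeffs, con.sense, con.rhs, name=con.name)
        res = relaxed.solve()
        if res.status == INFEASIBLE:
            return "stoichiometry/bounds (infeasible even without enzyme constraints)"
        return "enzyme capacity constraints"


def build_moment(
    model: MetabolicModel, params: EnzymeParams, medium: Medium
) -> MomentProblem:
    """Assemble the MOMENT LP for one model/parameter-set/medium triple."""
    return MomentProblem(model, params, medium)


def solve_moment(problem: MomentProblem, parsimonious: bool = False) -> MomentSolution:
    """Solve a built MOMENT problem to proven optimality.

    With ``parsimonious=True`` a secondary LP minimizes total enzyme mass
    at the optimal growth rate, yielding a canonical allocation when the
    optimum in ``g`` is degenerate (needed for enzyme-level predictions).
    """
    res = problem.lp.solve()
    if res.status == INFEASIBLE:
        return MomentSolution(
            status=INFEASIBLE, growth=None,
            infeasibility_hint=problem._infeasibility_hint(),
        )
    if res.status == UNBOUNDED:
        return MomentSolution(
            status=UNBOUNDED, growth=None,
            infeasibility_hint=(
                "growth unbounded: a biomass route has no capacity row or "
                "uptake bound (check GPR-less cycles)"
            ),
        )
    growth = res.objective
    values = res.values
    if parsimonious and problem.registry.gene_vars:
        biomass = problem.model.require_biomass()
        fix = problem.lp.add_constraint(
            problem.net_flux_expr(biomass), ">=", growth - 1e-9, name="fix-growth"
        )
        mass_obj = {
            var: problem.params.mw[gene]
            for gene, var in problem.registry.gene_vars.items()
        }
        problem.lp.set_objective(mass_obj, maximize=False)
        res2 = problem.lp.solve()
        problem.lp.remove_constraint(fix)
        obj = {problem._fwd[biomass]: 1.0}
        if biomass in problem._bwd:
            obj[problem._bwd[biomass]] = -1.0
        problem.lp.set_objective(obj, maximize=True)
        if res2.status == OPTIMAL:
            values = res2.values
    return problem._solution_from(values, growth)


def predict_growth_across_media(
    model: MetabolicModel,
    params: EnzymeParams,
    media: list[Medium],
    parsimonious: bool = False,
) -> pd.DataFrame:
    """Maximal growth rate per medium; one LP per medium.

    Returns a DataFrame (medium, growth, status) sorted by medium name.
    Per-medium failures are recorded in the status column, not raised.
    """
    names = [m.name for m in media]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate medium names: {dup}")
    rows = []
    for medium in media:
        try:
            sol = solve_moment(build_moment(model, params, medium), parsimonious)
            rows.append(
                {"medium": medium.name, "growth": sol.growth, "status": sol.status}
            )
        except (ValidationError, SolverError) as e:
            rows.append({"medium": medium.name, "growth": None, "status": f"error: {e}"})
    return (
        pd.DataFrame(rows, columns=["medium", "growth", "status"])
        .sort_values("medium")
        .reset_index(drop=True)
    )


def moment_fva(
    problem: MomentProblem,
    fix_growth_fraction: float = 1.0,
    targets: tuple[str, ...] = ("fluxes", "enzymes"),
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Variability of fluxes and/or enzyme concentrations at fixed growth.

    Growth is fixed to ``fix_growth_fraction`` times the optimum; each
    target variable is then minimized and maximized under the full set of
    enzyme-capacity constraints.  A variable is flagged ``unique`` when
    its range width is at most ``tol``.
    """
    if not (0 < fix_growth_fraction <= 1):
        raise ValidationError(
            f"fix_growth_fraction must be in (0, 1], got {fix_growth_fraction}"
        )
    base = solve_moment(problem)
    if not base.optimal:
        raise SolverError(f"base MOMENT problem is {base.status}", base.status)
    biomass = problem.model.require_biomass()
    fix = problem.lp.add_constraint(
        problem.net_flux_expr(biomass),
        "==",
        fix_growth_fraction * base.growth,
        name="fva-fix-growth",
    )
    entries: list[tuple[str, str, dict[str, float]]] = []
    if "fluxes" in targets:
        for r in problem.model.reactions:
            entries.append(("flux", r.id, problem.net_flux_expr(r.id)))
    if "enzymes" in targets:
        for gene in sorted(problem.registry.gene_vars):
            entries.append(("enzyme", gene, {problem.registry.gene_vars[gene]: 1.0}))
    rows = []
    try:
        for kind, name, expr in entries:
            lohi = []
            for maximize in (False, True):
                problem.lp.set_objective(expr, maximize=maximize)
                res = problem.lp.solve()
                if res.status != OPTIMAL:
                    raise SolverError(
                        f"FVA subproblem for {name!r} is {res.status}", res.status
                    )
                lohi.append(res.objective)
            lo, hi = lohi
            width = max(hi - lo, 0.0)
            rows.append(
                {
                    "kind": kind,
                    "id": name,
                    "min": lo,
                    "max": hi,
                    "width": width,
                    "unique": width <= tol,
                }
            )
    finally:
        problem.lp.remove_constraint(fix)
        obj = problem.net_flux_expr(biomass)
        problem.lp.set_objective(obj, maximize=True)
    return pd.DataFrame(rows, columns=["kind", "id", "min", "max", "width", "unique"])


def differential_enzymes(
    sol_low: MomentSolution,
    sol_high: MomentSolution,
    threshold: float = 1.0,
    pseudo_floor: float = 1e-9,
) -> tuple[pd.DataFrame, set[str]]:
    """Enzymes deviating from proportional scaling between two growth rates.

    For each gene expressed in both conditions the score is

        log2(g_high / g_low) - log2(mu_high / mu_low)

    i.e. the concentration fold change in excess of the growth-rate fold
    change; |score| >= threshold flags the gene.  Genes below
    ``pseudo_floor`` in either condition go to the returned ``undefined``
    set.  The table is sorted by |score| descending.
    """
    for name, sol in (("low", sol_low), ("high", sol_high)):
        if not sol.optimal:
            raise ValidationError(f"{name}-growth solution is {sol.status}")
        if not sol.growth or sol.growth <= 0:
            raise ValidationError(f"{name}-growth solution has zero growth")
    mu_term = math.log2(sol_high.growth / sol_low.growth)
    rows = []
    undefined: set[str] = set()
    for gene in sorted(set(sol_low.g) | set(sol_high.g)):
        lo = sol_low.g.get(gene, 0.0)
        hi = sol_high.g.get(gene, 0.0)
        if lo <= pseudo_floor or hi <= pseudo_floor:
            undefined.add(gene)
            continue
        score = math.log2(hi / lo) - mu_term
        rows.append(
            {
                "gene": gene,
                "g_low": lo,
                "g_high": hi,
                "score": score,
                "flagged": abs(score) >= threshold,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "g_low", "g_high", "score", "flagged"])
    if not df.empty:
        df = (
            df.reindex(df["score"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True)
        )
    return df, undefined
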