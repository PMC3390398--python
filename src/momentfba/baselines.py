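"""Stoichiometry-only reference methods.

These are the classical constraint-based analyses MOMENT is compared
against: plain FBA (maximal biomass at a bounded uptake), FBA at a fixed
measured growth rate, flux variability analysis, a molecular-crowding
variant (FBAwMC-style: one linear cost per unit flux, summing to a fixed
budget), least-squares fitting of a genome-scale flux distribution to a
set of measured fluxes, and the ATP-yield-per-flux-norm heuristic solved
as a series of quadratic programs over a trade-off parameter epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SolverError, ValidationError
from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LinearProgram, solve_qp
from .model import Medium, MetabolicModel

INF = math.inf


class FluxProblem:
    """FBA-style LP over a model + medium, reversibles optionally split."""

    def __init__(self, model: MetabolicModel, medium: Medium, split: bool = False):
        self.model = model
        self.medium = medium
        self.split = split
        self.lp = LinearProgram(name=f"fba:{model.id}:{medium.name}")
        self._fwd: dict[str, str] = {}
        self._bwd: dict[str, str] = {}
        ex_bounds = model.medium_bounds(medium)
        for r in model.reactions:
            lb, ub = ex_bounds.get(r.id, (r.lb, r.ub))
            if split and lb < 0:
                self._fwd[r.id] = self.lp.add_var(f"vf:{r.id}", 0.0, max(ub, 0.0))
                self._bwd[r.id] = self.lp.add_var(f"vb:{r.id}", 0.0, -lb)
            else:
                self._fwd[r.id] = self.lp.add_var(f"v:{r.id}", lb, ub)
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

    def net_flux_expr(self, rid: str) -> dict[str, float]:
        expr = {self._fwd[rid]: 1.0}
        if rid in self._bwd:
            expr[self._bwd[rid]] = -1.0
        return expr

    def uptake_expr(self) -> dict[str, float]:
        """Total uptake flux over the medium's open exchanges."""
        expr: dict[str, float] = {}
        for rid in sorted(self.medium.open_exchanges):
            d = self.model.uptake_direction(rid)
            if self.split and rid in self._bwd:
                var = self._fwd[rid] if d > 0 else self._bwd[rid]
                expr[var] = expr.get(var, 0.0) + 1.0
            else:
                expr[self._fwd[rid]] = expr.get(self._fwd[rid], 0.0) + d
        return expr

    def cap_uptake(self, bound: float) -> None:
        """Apply an uptake cap to open exchanges without an explicit bound."""
        for rid in self.medium.open_exchanges:
            if rid in self.medium.uptake_bound:
                continue
            d = self.model.uptake_direction(rid)
            if self.split and rid in self._bwd:
                var = self._fwd[rid] if d > 0 else self._bwd[rid]
                lb, ub = self.lp.get_bounds(var)
                self.lp.set_bounds(var, lb, min(ub, bound))
            else:
                var = self._fwd[rid]
                lb, ub = self.lp.get_bounds(var)
                if d > 0:
                    self.lp.set_bounds(var, lb, min(ub, bound))
                else:
                    self.lp.set_bounds(var, max(lb, -bound), ub)

    def net_fluxes(self, values: dict[str, float]) -> dict[str, float]:
        out = {}
        for r in self.model.reactions:
            v = values[self._fwd[r.id]]
            if r.id in self._bwd:
                v -= values[self._bwd[r.id]]
            out[r.id] = v
        return out

    def solve_or_raise(self, what: str):
        res = self.lp.solve()
        if res.status == INFEASIBLE:
            raise SolverError(f"{what}: problem infeasible", INFEASIBLE)
        if res.status == UNBOUNDED:
            raise SolverError(
                f"{what}: objective unbounded — an exchange or internal cycle "
                "carries unlimited flux; add an uptake bound",
                UNBOUNDED,
            )
        return res


@dataclass
class FBAResult:
    v: dict[str, float]
    objective: float
    biomass_yield: float | None = None


def fba(
    model: MetabolicModel,
    medium: Medium,
    uptake_bound: float | None = None,
    objective: str | None = None,
) -> FBAResult:
    """Maximize an objective flux (default biomass) under mass balance.

    ``uptake_bound`` caps uptake at each open exchange lacking an explicit
    medium bound; the reported biomass yield is objective / uptake_bound.
    """
    objective = objective or model.require_biomass()
    if objective not in model:
        raise ValidationError(f"objective reaction {objective!r} not in model")
    prob = FluxProblem(model, medium)
    if uptake_bound is not None:
        if uptake_bound <= 0:
            raise ValidationError(f"uptake_bound must be > 0, got {uptake_bound}")
        prob.cap_uptake(uptake_bound)
    prob.lp.set_objective(prob.net_flux_expr(objective), maximize=True)
    res = prob.solve_or_raise("FBA")
    return FBAResult(
        v=prob.net_fluxes(res.values),
        objective=res.objective,
        biomass_yield=(res.objective / uptake_bound) if uptake_bound else None,
    )


def fba_fixed_growth(
    model: MetabolicModel, medium: Medium, growth: float
) -> dict[str, float]:
    """Flux distribution at a fixed (measured) growth rate, maximal yield.

    Maximal yield at fixed growth is implemented as minimal carbon uptake;
    a secondary minimization of total absolute flux makes the returned
    vector determinate.
    """
    if growth < 0:
        raise ValidationError(f"growth must be >= 0, got {growth}")
    prob = FluxProblem(model, medium, split=True)
    biomass = model.require_biomass()
    prob.lp.add_constraint(prob.net_flux_expr(biomass), "==", growth, name="fix-growth")
    uptake = prob.uptake_expr()
    prob.lp.set_objective(uptake, maximize=False)
    res = prob.solve_or_raise(f"FBA at fixed growth {growth}")
    min_uptake = res.objective
    prob.lp.add_constraint(uptake, "<=", min_uptake + 1e-9, name="fix-uptake")
    prob.lp.set_objective({v: 1.0 for v in prob.lp.variables}, maximize=False)
    res = prob.solve_or_raise("parsimony step")
    return prob.net_fluxes(res.values)


def fva(
    model: MetabolicModel,
    medium: Medium,
    objective_fraction: float = 1.0,
    tol: float = 1e-6,
    uptake_bound: float | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-reaction flux ranges at >= objective_fraction of optimal biomass.

    Returns the range table and the set of uniquely determined reactions
    (range width <= tol).
    """
    base = fba(model, medium, uptake_bound=uptake_bound)
    prob = FluxProblem(model, medium)
    if uptake_bound is not None:
        prob.cap_uptake(uptake_bound)
    biomass = model.require_biomass()
    prob.lp.add_constraint(
        prob.net_flux_expr(biomass),
        ">=",
        objective_fraction * base.objective,
        name="fva-objective",
    )
    rows = []
    unique: set[str] = set()
    for r in model.reactions:
        expr = prob.net_flux_expr(r.id)
        lohi = []
        for maximize in (False, True):
            prob.lp.set_objective(expr, maximize=maximize)
            res = prob.solve_or_raise(f"FVA for {r.id}")
            lohi.append(res.objective)
        lo, hi = lohi
        width = max(hi - lo, 0.0)
        rows.append({"reaction": r.id, "min": lo, "max": hi, "width": width})
        if width <= tol:
            unique.add(r.id)
    df = pd.DataFrame(rows, columns=["reaction", "min", "max", "width"])
    df["unique"] = df["reaction"].isin(unique)
    return df, unique


# ---------------------------------------------------------------------------
# quadratic programs
# ---------------------------------------------------------------------------

@dataclass
class FluxFitResult:
    v: dict[str, float]
    sse: float
    measured_ids: list[str] = field(default_factory=list)


def _feasible_point(prob: FluxProblem) -> np.ndarray:
    prob.lp.set_objective({}, maximize=False)
    res = prob.solve_or_raise("feasibility step")
    return np.array([res.values[v] for v in prob.lp.variables])


def _qp_arrays(prob: FluxProblem):
    c, A_ub, b_ub, A_eq, b_eq, bounds, idx = prob.lp.arrays()
    if A_ub is not None:
        raise SolverError("QP path expects equality-and-bounds form")
    return A_eq, b_eq, bounds, idx


def fit_fluxes_qp(
    model: MetabolicModel,
    measured: dict[str, float],
    medium: Medium | None = None,
) -> FluxFitResult:
    """Least-squares fit of a full flux distribution to measured fluxes.

    Minimizes the squared Euclidean distance between predicted and
    measured fluxes over the measured set, subject to mass balance and
    bounds; unmeasured fluxes are free (unpenalized).
    """
    if not measured:
        raise ValidationError("no measured fluxes supplied")
    missing = sorted(set(measured) - set(model.reaction_ids))
    if missing:
        raise ValidationError(f"measured ids not in model: {missing}")
    medium = medium or Medium("all-open", model.exchange_reactions)
    prob = FluxProblem(model, medium)
    A_eq, b_eq, bounds, idx = _qp_arrays(prob)
    n = len(prob.lp.variables)
    q = np.zeros(n)
    lin = np.zeros(n)
    for rid, m in measured.items():
        j = idx[prob._fwd[rid]]
        q[j] = 1.0
        lin[j] = -2.0 * m
    x0 = _feasible_point(prob)
    x = solve_qp(q, lin, A_eq, b_eq, bounds, x0)
    values = {v: float(x[idx[v]]) for v in prob.lp.variables}
    v = prob.net_fluxes(values)
    sse = sum((v[rid] - m) ** 2 for rid, m in measured.items())
    return FluxFitResult(v=v, sse=float(sse), measured_ids=sorted(measured))


@dataclass
class AtpScanResult:
    v: dict[str, float]
    eps: float
    ratio: float
    atp_flux: float
    flux_square_sum: float


def max_atp_per_flux_square(
    model: MetabolicModel,
    medium: Medium,
    uptake_fixed: float,
    atp_reaction: str,
    eps_grid: tuple[float, float, int] = (0.5, 1.5, 10000),
) -> AtpScanResult:
    """Flux distribution maximizing ATP yield per sum of squared fluxes.

    The ratio objective v_ATP / sum_j v_j^2 is non-convex; following the
    standard reformulation it is scanned as a series of concave QPs
    maximize eps * v_ATP - sum_j v_j^2 over a grid of eps values
    (default 10000 points in [0.5, 1.5]), keeping the solution with the
    best true ratio.  Uptake is fixed because the ratio is otherwise
    scale-degenerate.
    """
    if atp_reaction not in model:
        raise ValidationError(f"ATP drain reaction {atp_reaction!r} not in model")
    if uptake_fixed <= 0:
        raise ValidationError(f"uptake_fixed must be > 0, got {uptake_fixed}")
    lo, hi, n = eps_grid
    if n < 1:
        raise ValidationError("eps grid needs at least one point")
    prob = FluxProblem(model, medium)
    prob.lp.add_constraint(prob.uptake_expr(), "==", uptake_fixed, name="fix-uptake")
    A_eq, b_eq, bounds, idx = _qp_arrays(prob)
    nvar = len(prob.lp.variables)
    atp_j = idx[prob._fwd[atp_reaction]]
    x0 = _feasible_point(prob)
    best: AtpScanResult | None = None
    eps_values = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    q = np.ones(nvar)
    for eps in eps_values:
        lin = np.zeros(nvar)
        lin[atp_j] = -eps
        x = solve_qp(q, lin, A_eq, b_eq, bounds, x0)
        x0 = x  # warm-start the next grid point
        atp = float(x[atp_j])
        ss = float(x @ x)
        ratio = atp / ss if ss > 1e-12 else 0.0
        if best is None or ratio > best.ratio:
            values = {v: float(x[idx[v]]) for v in prob.lp.variables}
            best = AtpScanResult(
                v=prob.net_fluxes(values),
                eps=float(eps),
                ratio=ratio,
                atp_flux=atp,
                flux_square_sum=ss,
            )
    return best


# ---------------------------------------------------------------------------
# molecular crowding
# ---------------------------------------------------------------------------

@dataclass
class CrowdingParams:
    """Per-reaction crowding cost a_j (h*gDW/mmol): sum_j a_j |v_j| <= budget."""

    coefficients: dict[str, float] = field(default_factory=dict)
    budget: float = 1.0

    def __post_init__(self):
        for rid, a in self.coefficients.items():
            if a < 0:
                raise ValidationError(f"crowding coefficient for {rid!r} < 0")

    @classmethod
    def from_enzyme_params(cls, model: MetabolicModel, params) -> "CrowdingParams":
        """Derive a_j = MW_heaviest_gene / (kcat_j * C) for GPR reactions.

        This gives the crowding baseline the very same kcat/MW tables used
        by the enzyme-constrained model, without the gene-reaction
        structure (each reaction pays for its own enzyme pool).
        """
        coeffs = {}
        for r in model.reactions:
            if r.gpr is None or r.id not in params.kcat:
                continue
            mws = [params.mw[g] for g in r.genes if g in params.mw]
            if not mws:
                continue
            coeffs[r.id] = max(mws) / (params.kcat[r.id] * params.capacity_C)
        return cls(coefficients=coeffs)


def fbawmc(
    model: MetabolicModel, medium: Medium, crowding: CrowdingParams
) -> tuple[dict[str, float], float]:
    """Maximize biomass under a single linear flux-cost (crowding) budget."""
    prob = FluxProblem(model, medium, split=True)
    biomass = model.require_biomass()
    coeffs: dict[str, float] = {}
    for rid, a in crowding.coefficients.items():
        if a == 0:
            continue
        if rid not in model:
            raise ValidationError(f"crowding coefficient for unknown reaction {rid!r}")
        coeffs[prob._fwd[rid]] = a
        if rid in prob._bwd:
            coeffs[prob._bwd[rid]] = a
    if coeffs:
        prob.lp.add_constraint(coeffs, "<=", crowding.budget, name="crowding")
    prob.lp.set_objective(prob.net_flux_expr(biomass), maximize=True)
    res = prob.solve_or_raise("FBAwMC")
    return prob.net_fluxes(res.values), res.objective
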