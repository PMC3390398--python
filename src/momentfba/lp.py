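"""A thin named-variable layer over ``scipy.optimize.linprog`` (HiGHS).

All optimizations in this package are linear programs over a few kinds of
named variables (fluxes, enzyme concentrations, auxiliary complex
variables).  This module provides the bookkeeping: variables with bounds,
named constraint rows, an objective, and a solve that returns a status in
{optimal, infeasible, unbounded} plus a value per variable.

Quadratic objectives (flux fitting, ATP-per-flux-norm) are handled by
:func:`solve_qp`, which runs SLSQP on the same constraint arrays; problems
here are small and strictly convex, where SLSQP is dependable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import SolverError

INF = math.inf

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: default feasibility / optimality tolerance passed to HiGHS
FEAS_TOL = 1e-9


@dataclass
class _Constraint:
    coeffs: dict[str, float]
    sense: str  # "<=" or "=="
    rhs: float
    name: str


@dataclass
class LPResult:
    status: str
    objective: float | None
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, var: str) -> float:
        return self.values[var]


class LinearProgram:
    """Incrementally built LP; solve() may be called repeatedly after edits."""

    def __init__(self, name: str = "lp"):
        self.name = name
        self._vars: list[str] = []
        self._bounds: dict[str, tuple[float, float]] = {}
        self._constraints: list[_Constraint] = []
        self._objective: dict[str, float] = {}
        self._maximize = True

    # -- construction -------------------------------------------------------
    def add_var(self, name: str, lb: float = 0.0, ub: float = INF) -> str:
        if name in self._bounds:
            raise ValueError(f"duplicate variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r}: lb {lb} > ub {ub}")
        self._vars.append(name)
        self._bounds[name] = (lb, ub)
        return name

    def has_var(self, name: str) -> bool:
        return name in self._bounds

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        if name not in self._bounds:
            raise KeyError(name)
        if lb > ub:
            raise ValueError(f"variable {name!r}: lb {lb} > ub {ub}")
        self._bounds[name] = (lb, ub)

    def get_bounds(self, name: str) -> tuple[float, float]:
        return self._bounds[name]

    def add_constraint(
        self, coeffs: dict[str, float], sense: str, rhs: float, name: str | None = None
    ) -> str:
        if sense not in ("<=", "==", ">="):
            raise ValueError(f"bad sense {sense!r}")
        if sense == ">=":  # normalize
            coeffs = {k: -c for k, c in coeffs.items()}
            rhs, sense = -rhs, "<="
        for k in coeffs:
            if k not in self._bounds:
                raise KeyError(f"constraint references unknown variable {k!r}")
        cname = name or f"c{len(self._constraints)}"
        self._constraints.append(_Constraint(dict(coeffs), sense, float(rhs), cname))
        return cname

    def remove_constraint(self, name: str) -> None:
        self._constraints = [c for c in self._constraints if c.name != name]

    def set_objective(self, coeffs: dict[str, float], maximize: bool = True) -> None:
        self._objective = dict(coeffs)
        self._maximize = maximize

    @property
    def variables(self) -> list[str]:
        return list(self._vars)

    @property
    def constraints(self) -> list[_Constraint]:
        return list(self._constraints)

    # -- array form ---------------------------------------------------------
    def arrays(self):
        idx = {v: i for i, v in enumerate(self._vars)}
        n = len(self._vars)
        c = np.zeros(n)
        for k, coef in self._objective.items():
            c[idx[k]] = coef
        if self._maximize:
            c = -c
        A_ub, b_ub, A_eq, b_eq = [], [], [], []
        for con in self._constraints:
            row = np.zeros(n)
            for k, coef in con.coeffs.items():
                row[idx[k]] = coef
            if con.sense == "<=":
                A_ub.append(row)
                b_ub.append(con.rhs)
            else:
                A_eq.append(row)
                b_eq.append(con.rhs)
        bounds = [self._bounds[v] for v in self._vars]
        return (
            c,
            np.array(A_ub) if A_ub else None,
            np.array(b_ub) if b_ub else None,
            np.array(A_eq) if A_eq else None,
            np.array(b_eq) if b_eq else None,
            bounds,
            idx,
        )

    # -- solving ------------------------------------------------------------
    def solve(self) -> LPResult:
        c, A_ub, b_ub, A_eq, b_eq, bounds, idx = self.arrays()
        res = optimize.linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
            options={
                "primal_feasibility_tolerance": FEAS_TOL,
                "dual_feasibility_tolerance": FEAS_TOL,
            },
        )
        if res.status == 2:
            return LPResult(INFEASIBLE, None)
        if res.status == 3:
            return LPResult(UNBOUNDED, None)
        if res.status != 0:
            raise SolverError(f"LP {self.name!r} solver failure: {res.message}")
        obj = float(res.fun)
        if self._maximize:
            obj = -obj
        values = {v: float(res.x[idx[v]]) for v in self._vars}
        return LPResult(OPTIMAL, obj, values)

    def binding_constraints(self, values: dict[str, float], tol: float = 1e-6):
        """Names of inequality rows tight at the given point."""
        out = []
        for con in self._constraints:
            lhs = sum(coef * values[k] for k, coef in con.coeffs.items())
            if con.sense == "<=" and abs(lhs - con.rhs) <= tol:
                out.append(con.name)
        return out

    # -- export -------------------------------------------------------------
    def to_lp_format(self) -> str:
        """CPLEX-LP-style text form of the problem, for debugging."""
        lines = ["Maximize" if self._maximize else "Minimize"]
        lines.append(" obj: " + _expr(self._objective))
        lines.append("Subject To")
        for con in self._constraints:
            op = "<=" if con.sense == "<=" else "="
            lines.append(f" {con.name}: {_expr(con.coeffs)} {op} {con.rhs:g}")
        lines.append("Bounds")
        for v in self._vars:
            lb, ub = self._bounds[v]
            lo = "-inf" if lb == -INF else f"{lb:g}"
            hi = "+inf" if ub == INF else f"{ub:g}"
            lines.append(f" {lo} <= {v} <= {hi}")
        lines.append("End")
        return "\n".join(lines) + "\n"


def _expr(coeffs: dict[str, float]) -> str:
    parts = []
    for k, c in coeffs.items():
        sign = "+" if c >= 0 else "-"
        parts.append(f"{sign} {abs(c):g} {k}")
    return " ".join(parts) if parts else "0"


def solve_qp(
    q_diag: np.ndarray,
    lin: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    bounds: list[tuple[float, float]],
    x0: np.ndarray,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize x' diag(q) x + lin' x subject to A_eq x = b_eq and bounds.

    ``q_diag >= 0`` (convex).  Uses SLSQP from a feasible start ``x0``;
    raises :class:`SolverError` if the solver does not converge.
    """
    q_diag = np.asarray(q_diag, dtype=float)
    lin = np.asarray(lin, dtype=float)

    def fun(x):
        return float(x @ (q_diag * x) + lin @ x)

    def jac(x):
        return 2.0 * q_diag * x + lin

    cons = []
    if A_eq is not None and len(A_eq):
        A_eq = np.asarray(A_eq, dtype=float)
        b_eq = np.asarray(b_eq, dtype=float)
        cons.append(
            {"type": "eq", "fun": lambda x: A_eq @ x - b_eq, "jac": lambda x: A_eq}
        )
    slsqp_bounds = [
        (None if lb == -INF else lb, None if ub == INF else ub) for lb, ub in bounds
    ]
    res = optimize.minimize(
        fun,
        np.asarray(x0, dtype=float),
        jac=jac,
        bounds=slsqp_bounds,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": tol},
    )
    if not res.success:
        raise SolverError(f"QP failed: {res.message}")
    return np.asarray(res.x, dtype=float)
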