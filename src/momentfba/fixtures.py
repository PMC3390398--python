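"""Toy models with known optima, and a brute-force LP oracle.

Every toy is a short pathway from one uptake exchange to a biomass
drain, with enzymes attached through GPR patterns whose enzyme-capacity
optimum has a closed form:

* ``chain``:    growth = C / sum_j (MW_j / kcat_j)
  (one gene per step; equal flux v through all steps needs
  g_j = v/kcat_j, so the mass row pins v),
* ``parallel_isozyme``: growth = kcat * C / min(MW)
  (all mass goes to the lightest isozyme),
* ``complex``:  growth = kcat * C / sum(MW)
  (1:1 subunits; the scarcest subunit limits the complex),
* ``branched``: growth = C * max_j (kcat_j / MW_j)
  (two independent one-gene routes; best mass-efficiency wins),
* ``mixed_gpr``: growth = kcat * C * max(1/(MW_a + MW_b), 1/MW_c)
  for the rule ``(a and b) or c``.

The oracle enumerates basic feasible points of small LPs directly from
the constraint arrays, independently of the HiGHS-based solve path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .enzyme import EnzymeParams
from .errors import ValidationError
from .gpr import parse_gpr
from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LinearProgram
from .model import Medium, MetabolicModel, Reaction

INF = math.inf

TOPOLOGIES = ("chain", "parallel_isozyme", "complex", "branched", "mixed_gpr")


@dataclass
class ToySpec:
    """Recipe for one toy model (kcats in 1/h, MWs in g/mmol)."""

    topology: str = "chain"
    n_steps: int = 1
    kcats: tuple[float, ...] = (100.0,)
    mws: tuple[float, ...] = (1.0,)
    capacity_C: float = 1.0
    uptake_bound: float | None = None

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology!r}")


@dataclass
class ToyModel:
    model: MetabolicModel
    params: EnzymeParams
    medium: Medium
    analytic_optimum: float | None = None
    spec: ToySpec | None = None


def _toy(reactions, biomass, kcat, mw, C, medium_bound=None) -> ToyModel:
    model = MetabolicModel(id="toy", reactions=reactions, biomass_reaction=biomass)
    params = EnzymeParams(kcat=kcat, mw=mw, capacity_C=C)
    bound = {} if medium_bound is None else {"EX_src": medium_bound}
    medium = Medium("src", frozenset({"EX_src"}), bound)
    return ToyModel(model=model, params=params, medium=medium)


def make_toy(spec: ToySpec) -> ToyModel:
    """Build the toy model for ``spec`` with its analytic optimum attached."""
    C = spec.capacity_C
    if spec.topology == "chain":
        n = spec.n_steps
        if len(spec.kcats) != n or len(spec.mws) != n:
            raise ValidationError("chain needs one kcat and one MW per step")
        reactions = [Reaction("EX_src", {"m0": 1.0})]
        kcat, mw = {}, {}
        for j in range(n):
            rid, gene = f"R{j + 1}", f"g{j + 1}"
            reactions.append(
                Reaction(rid, {f"m{j}": -1.0, f"m{j + 1}": 1.0}, gpr=parse_gpr(gene))
            )
            kcat[rid] = spec.kcats[j]
            mw[gene] = spec.mws[j]
        reactions.append(Reaction("BM", {f"m{n}": -1.0}))
        toy = _toy(reactions, "BM", kcat, mw, C, spec.uptake_bound)
        toy.analytic_optimum = C / sum(w / k for w, k in zip(spec.mws, spec.kcats))
    elif spec.topology == "parallel_isozyme":
        (k,) = spec.kcats[:1]
        reactions = [
            Reaction("EX_src", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "b": 1.0}, gpr=parse_gpr("gA or gB")),
            Reaction("BM", {"b": -1.0}),
        ]
        mw = {"gA": spec.mws[0], "gB": spec.mws[1]}
        toy = _toy(reactions, "BM", {"R1": k}, mw, C, spec.uptake_bound)
        toy.analytic_optimum = k * C / min(spec.mws[:2])
    elif spec.topology == "complex":
        (k,) = spec.kcats[:1]
        reactions = [
            Reaction("EX_src", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "b": 1.0}, gpr=parse_gpr("gA and gB")),
            Reaction("BM", {"b": -1.0}),
        ]
        mw = {"gA": spec.mws[0], "gB": spec.mws[1]}
        toy = _toy(reactions, "BM", {"R1": k}, mw, C, spec.uptake_bound)
        toy.analytic_optimum = k * C / sum(spec.mws[:2])
    elif spec.topology == "branched":
        k1, k2 = spec.kcats[:2]
        reactions = [
            Reaction("EX_src", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "b": 1.0}, gpr=parse_gpr("gA")),
            Reaction("R2", {"s": -1.0, "b": 1.0}, gpr=parse_gpr("gB")),
            Reaction("BM", {"b": -1.0}),
        ]
        mw = {"gA": spec.mws[0], "gB": spec.mws[1]}
        toy = _toy(reactions, "BM", {"R1": k1, "R2": k2}, mw, C, spec.uptake_bound)
        toy.analytic_optimum = C * max(k1 / spec.mws[0], k2 / spec.mws[1])
    elif spec.topology == "mixed_gpr":
        (k,) = spec.kcats[:1]
        wa, wb, wc = spec.mws[:3]
        reactions = [
            Reaction("EX_src", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "b": 1.0}, gpr=parse_gpr("(gA and gB) or gC")),
            Reaction("BM", {"b": -1.0}),
        ]
        mw = {"gA": wa, "gB": wb, "gC": wc}
        toy = _toy(reactions, "BM", {"R1": k}, mw, C, spec.uptake_bound)
        toy.analytic_optimum = k * C * max(1.0 / (wa + wb), 1.0 / wc)
    else:  # pragma: no cover - guarded by ToySpec
        raise ValidationError(spec.topology)
    toy.spec = spec
    return toy


def chain_toy(kcats=(100.0,), mws=(1.0,), C=1.0, uptake_bound=None) -> ToyModel:
    return make_toy(
        ToySpec("chain", len(kcats), tuple(kcats), tuple(mws), C, uptake_bound)
    )


def isozyme_toy(kcat=10.0, mws=(1.0, 2.0), C=1.0) -> ToyModel:
    return make_toy(ToySpec("parallel_isozyme", 1, (kcat,), tuple(mws), C))


def complex_toy(kcat=10.0, mws=(1.0, 3.0), C=1.0) -> ToyModel:
    return make_toy(ToySpec("complex", 1, (kcat,), tuple(mws), C))


# ---------------------------------------------------------------------------
# brute-force LP oracle
# ---------------------------------------------------------------------------

_BOX = 1e6          # artificial bound standing in for infinity
_FEAS_TOL = 1e-7
_MAX_BASES = 300_000


@dataclass
class OracleResult:
    status: str
    objective: float | None
    x: dict[str, float] = field(default_factory=dict)


def brute_force_lp(lp: LinearProgram) -> OracleResult:
    """Solve a small LP by enumerating basic feasible points.

    Every equality row is kept active; each choice of the remaining
    active set among the inequality rows (including bound rows, with an
    artificial box replacing infinite bounds) yields a candidate square
    system.  Feasible candidates are scored by the objective; an optimum
    that only exists on the artificial box is reported as unbounded.
    Intended for fixtures with at most ~10 variables.
    """
    c, A_ub, b_ub, A_eq, b_eq, bounds, idx = lp.arrays()
    n = len(c)
    # lp.arrays() yields a minimization vector c; vertices are scored by
    # -c.x (so "better" is always larger), and the reported objective is
    # mapped back to the problem's own sense
    maximize = lp._maximize

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    artificial: list[bool] = []
    if A_ub is not None:
        for row, b in zip(A_ub, b_ub):
            rows.append(np.asarray(row, dtype=float))
            rhs.append(float(b))
            artificial.append(False)
    for j, (lb, ub) in enumerate(bounds):
        e = np.zeros(n)
        e[j] = 1.0
        rows.append(e.copy())
        rhs.append(float(ub) if ub != INF else _BOX)
        artificial.append(ub == INF)
        rows.append(-e)
        rhs.append(float(-lb) if lb != -INF else _BOX)
        artificial.append(lb == -INF)

    eq_rows = [] if A_eq is None else [np.asarray(r, dtype=float) for r in A_eq]
    eq_rhs = [] if b_eq is None else [float(b) for b in b_eq]
    n_eq = len(eq_rows)
    k = n - n_eq
    if k < 0:
        k = 0
    if math.comb(len(rows), k) > _MAX_BASES:
        raise ValidationError(
            f"oracle refuses {math.comb(len(rows), k)} candidate bases "
            f"({n} vars, {len(rows)} inequality rows)"
        )

    A_all = np.array(rows) if rows else np.zeros((0, n))
    b_all = np.array(rhs)

    def feasible(x: np.ndarray) -> bool:
        if rows and np.any(A_all @ x > b_all + _FEAS_TOL):
            return False
        for row, b in zip(eq_rows, eq_rhs):
            if abs(row @ x - b) > _FEAS_TOL:
                return False
        return True

    best_true: tuple[float, np.ndarray] | None = None
    best_any: tuple[float, np.ndarray] | None = None
    found_feasible = False
    for combo in combinations(range(len(rows)), k):
        M = np.array(eq_rows + [rows[i] for i in combo]).reshape(n_eq + k, n)
        if M.shape[0] != n:
            continue
        rv = np.array(eq_rhs + [rhs[i] for i in combo])
        try:
            x = np.linalg.solve(M, rv)
        except np.linalg.LinAlgError:
            continue
        if not feasible(x):
            continue
        found_feasible = True
        obj = -float(c @ x)
        on_box = any(
            artificial[i] and abs(rows[i] @ x - rhs[i]) <= _FEAS_TOL for i in combo
        )
        if best_any is None or obj > best_any[0]:
            best_any = (obj, x)
        if not on_box and (best_true is None or obj > best_true[0]):
            best_true = (obj, x)

    if not found_feasible:
        return OracleResult(INFEASIBLE, None)
    scale = 1.0 + (abs(best_true[0]) if best_true else 0.0)
    if best_true is None or best_any[0] > best_true[0] + 1e-6 * scale:
        return OracleResult(UNBOUNDED, None)
    obj, x = best_true
    if not maximize:
        obj = -obj
    inv = {j: v for v, j in idx.items()}
    return OracleResult(OPTIMAL, obj, {inv[j]: float(x[j]) for j in range(n)})


# ---------------------------------------------------------------------------
# random suite
# ---------------------------------------------------------------------------

def make_random_suite(n_models: int, seed: int) -> list[ToyModel]:
    """Reproducible random toys mixing all GPR patterns.

    Parameter ranges: kcat log-uniform in [10, 1000] 1/h, MW uniform in
    [0.5, 5] g/mmol, capacity uniform in [0.1, 1] g/gDW.  Every model has
    a complete route to biomass and therefore a finite positive optimum.
    """
    rng = np.random.default_rng(seed)
    suite: list[ToyModel] = []
    for _ in range(n_models):
        topology = TOPOLOGIES[rng.integers(len(TOPOLOGIES))]
        n_steps = int(rng.integers(1, 4)) if topology == "chain" else 1
        n_k = {"chain": n_steps, "branched": 2}.get(topology, 1)
        n_w = {"chain": n_steps, "mixed_gpr": 3}.get(topology, 2)
        kcats = tuple(10.0 ** rng.uniform(1, 3, size=n_k))
        mws = tuple(rng.uniform(0.5, 5.0, size=n_w))
        C = float(rng.uniform(0.1, 1.0))
        suite.append(make_toy(ToySpec(topology, n_steps, kcats, mws, C)))
    return suite
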