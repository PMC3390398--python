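"""Core model containers: reactions, the stoichiometric model, and media.

Unit conventions, fixed package-wide:

* flux ``v``            mmol/gDW/h
* enzyme concentration  mmol/gDW
* kcat                  1/h  (files carry 1/s; converted at the I/O boundary)
* molecular weight      g/mmol (files carry Da; converted at the I/O boundary)
* enzyme capacity C     g/gDW, a dimensionless mass fraction

so that MW * g is directly a mass fraction and the solvent-capacity
constraint sum_i MW_i * g_i <= C needs no further conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .gpr import GPRNode

INF = math.inf


@dataclass
class Reaction:
    """A single reaction: stoichiometry, bounds, and its GPR rule.

    ``metabolites`` maps metabolite id -> stoichiometric coefficient
    (negative = consumed).  ``reversible`` is inferred from ``lb < 0``
    unless set explicitly.
    """

    id: str
    metabolites: dict[str, float] = field(default_factory=dict)
    lb: float = 0.0
    ub: float = INF
    gpr: GPRNode | None = None
    ec_numbers: tuple[str, ...] = ()

    def __post_init__(self):
        if self.lb > self.ub:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lb} > upper bound {self.ub}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.metabolites) == 1

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr is not None else frozenset()


@dataclass
class Medium:
    """A named growth medium: which exchange reactions may carry uptake.

    ``uptake_bound`` optionally caps the uptake flux per open exchange
    (default unbounded).  Exchanges not listed have their uptake direction
    closed; secretion always stays open.
    """

    name: str
    open_exchanges: frozenset[str] = frozenset()
    uptake_bound: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.open_exchanges = frozenset(self.open_exchanges)


class MetabolicModel:
    """A validated stoichiometric model.

    Wraps an ordered reaction list with metabolite bookkeeping, a sparse
    stoichiometric matrix built on demand, and identification of the
    biomass and exchange reactions.
    """

    def __init__(
        self,
        id: str,
        reactions: list[Reaction],
        biomass_reaction: str | None = None,
        metabolites: list[str] | None = None,
    ):
        self.id = id
        self.reactions = list(reactions)
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError(f"model {id!r}: duplicate reaction ids")
        seen: dict[str, None] = {}
        for r in self.reactions:
            for m in r.metabolites:
                seen.setdefault(m, None)
        self.metabolites = list(metabolites) if metabolites is not None else list(seen)
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError(f"model {id!r}: duplicate metabolite ids")
        self.biomass_reaction = biomass_reaction
        self._S: sparse.csr_matrix | None = None
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_reactions(self) -> frozenset[str]:
        return frozenset(r.id for r in self.reactions if r.is_exchange)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.genes)
        return frozenset(out)

    @property
    def S(self) -> sparse.csr_matrix:
        """Sparse N x M stoichiometric matrix (metabolites x reactions)."""
        if self._S is None:
            rows, cols, vals = [], [], []
            for j, r in enumerate(self.reactions):
                for m, coef in r.metabolites.items():
                    if coef != 0:
                        rows.append(self._met_index[m])
                        cols.append(j)
                        vals.append(float(coef))
            self._S = sparse.csr_matrix(
                (vals, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)),
            )
        return self._S

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for r in self.reactions:
            for m in r.metabolites:
                if m not in self._met_index:
                    raise ValidationError(
                        f"reaction {r.id!r} references unknown metabolite {m!r}"
                    )
        if self.biomass_reaction is not None:
            if self.biomass_reaction not in self._rxn_index:
                raise ValidationError(
                    f"biomass reaction {self.biomass_reaction!r} not in model"
                )
            bm = self.reaction(self.biomass_reaction)
            if bm.lb < 0:
                raise ValidationError(
                    f"biomass reaction {bm.id!r} must be irreversible forward (lb >= 0)"
                )

    def require_biomass(self) -> str:
        if self.biomass_reaction is None:
            raise ValidationError(f"model {self.id!r} has no biomass reaction")
        return self.biomass_reaction

    def validate_medium(self, medium: Medium) -> None:
        bad = medium.open_exchanges - self.exchange_reactions
        if bad:
            raise ValidationError(
                f"medium {medium.name!r} opens non-exchange reactions: {sorted(bad)}"
            )

    def uptake_direction(self, rid: str) -> int:
        """+1 if forward flux imports the metabolite, -1 if backward does.

        An exchange reaction has a single stoichiometric entry; the uptake
        direction is the one that produces the metabolite inside the system.
        """
        r = self.reaction(rid)
        if not r.is_exchange:
            raise ValidationError(f"reaction {rid!r} is not an exchange reaction")
        (coef,) = r.metabolites.values()
        return 1 if coef > 0 else -1

    def medium_bounds(self, medium: Medium) -> dict[str, tuple[float, float]]:
        """Effective (lb, ub) per exchange reaction under ``medium``.

        Closed exchanges get their uptake direction clamped to zero
        (secretion stays open); open ones keep or cap uptake at the
        medium's per-exchange bound.
        """
        self.validate_medium(medium)
        out: dict[str, tuple[float, float]] = {}
        for rid in self.exchange_reactions:
            r = self.reaction(rid)
            lb, ub = r.lb, r.ub
            direction = self.uptake_direction(rid)
            if rid in medium.open_exchanges:
                cap = medium.uptake_bound.get(rid, INF)
                if direction > 0:
                    ub = min(ub, cap)
                else:
                    lb = max(lb, -cap)
            else:
                if direction > 0:
                    ub = min(ub, 0.0)
                else:
                    lb = max(lb, 0.0)
            out[rid] = (lb, ub)
        return out

    def mass_balance_residual(self, v: dict[str, float]) -> float:
        """Max |S.v| over metabolites for a flux vector keyed by reaction id."""
        x = np.array([v.get(r.id, 0.0) for r in self.reactions])
        if not len(self.metabolites):
            return 0.0
        return float(np.max(np.abs(self.S @ x)))
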