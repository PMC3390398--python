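"""Reading and writing models, media, and parameter tables.

Models come in two formats:

* a minimal JSON dialect compatible with the community (cobrapy) JSON
  schema — ``id``, ``metabolites``, ``reactions`` with ``metabolites``
  (id -> coefficient), ``lower_bound``/``upper_bound``,
  ``gene_reaction_rule`` and optionally ``objective_coefficient`` marking
  the biomass reaction;
* SBML Level 3 with the FBC extension (``geneProductAssociation``), read
  and written through cobrapy.

Parameter tables are two-column TSV/CSV with a header.  File units follow
database conventions (kcat in 1/s, molecular weight in Da) and are
converted to package units (1/h, g/mmol) on read.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .gpr import parse_gpr
from .model import Medium, MetabolicModel, Reaction

log = logging.getLogger(__name__)

_BIG = 1e6  # stand-in for +/- inf when a format needs finite bounds

#: file-unit -> package-unit conversion per table kind
_TABLE_KINDS = {
    "kcat": ("reaction", 3600.0),       # 1/s -> 1/h
    "mw": ("gene", 1e-3),               # Da -> g/mmol
    "fluxes": ("reaction", 1.0),        # mmol/gDW/h as-is
    "growth_rates": ("medium", 1.0),    # 1/h as-is
    "expression": ("gene", 1.0),        # arbitrary units as-is
}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from JSON or SBML.

    ``format`` is ``"json"`` or ``"sbml"``; inferred from the file suffix
    when omitted (``.json`` vs ``.xml``/``.sbml``).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValidationError(f"unknown model format {format!r}")


def _read_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed JSON model {path}: {e}") from None
    reactions = []
    biomass = data.get("biomass_reaction")
    for rd in data.get("reactions", []):
        if "id" not in rd:
            raise ValidationError(f"model {path}: reaction without an 'id'")
        lb = float(rd.get("lower_bound", 0.0))
        ub = float(rd.get("upper_bound", math.inf))
        rxn = Reaction(
            id=rd["id"],
            metabolites={m: float(c) for m, c in rd.get("metabolites", {}).items()},
            lb=lb,
            ub=ub,
            gpr=parse_gpr(rd.get("gene_reaction_rule", "")),
            ec_numbers=tuple(rd.get("ec_numbers", ())),
        )
        reactions.append(rxn)
        if biomass is None and float(rd.get("objective_coefficient", 0.0)) != 0.0:
            biomass = rd["id"]
    met_ids = [m["id"] for m in data.get("metabolites", [])] or None
    return MetabolicModel(
        id=data.get("id", path.stem),
        reactions=reactions,
        biomass_reaction=biomass,
        metabolites=met_ids,
    )


def _read_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cm = read_sbml_model(str(path))
        except Exception as e:
            raise ValidationError(f"malformed SBML model {path}: {e}") from None
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model (any source format) to a MetabolicModel."""
    biomass = None
    reactions = []
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass = r.id
        reactions.append(
            Reaction(
                id=r.id,
                metabolites={m.id: float(c) for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
            )
        )
    return MetabolicModel(id=cm.id or "model", reactions=reactions, biomass_reaction=biomass)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (infinite bounds capped at +/-1e6)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = max(r.lb, -_BIG)
        cr.upper_bound = min(r.ub, _BIG)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.metabolites.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.render()
    if model.biomass_reaction is not None:
        cm.objective = model.biomass_reaction
    return cm


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model to JSON (default) or SBML-FBC."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        data = {
            "id": model.id,
            "biomass_reaction": model.biomass_reaction,
            "metabolites": [{"id": m} for m in model.metabolites],
            "genes": [{"id": g} for g in sorted(model.genes)],
            "reactions": [
                {
                    "id": r.id,
                    "metabolites": r.metabolites,
                    "lower_bound": None if r.lb == -math.inf else r.lb,
                    "upper_bound": None if r.ub == math.inf else r.ub,
                    "gene_reaction_rule": r.gpr.render() if r.gpr else "",
                    "ec_numbers": list(r.ec_numbers),
                    "objective_coefficient": 1.0
                    if r.id == model.biomass_reaction
                    else 0.0,
                }
                for r in model.reactions
            ],
        }
        # JSON has no inf literal; None round-trips back to the defaults
        for rd in data["reactions"]:
            if rd["lower_bound"] is None:
                rd["lower_bound"] = -_BIG
            if rd["upper_bound"] is None:
                rd["upper_bound"] = _BIG
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))
    elif format == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValidationError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# keyed tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, kind: str) -> dict[str, float]:
    """Read a two-column keyed table, converting file units to package units.

    ``kind`` selects key semantics and unit conversion: ``kcat``
    (reaction, 1/s -> 1/h), ``mw`` (gene, Da -> g/mmol), ``fluxes``
    (reaction), ``growth_rates`` (medium), ``expression`` (gene).
    Duplicate keys and non-numeric values are errors; an empty table is
    returned as an empty mapping with a logged warning.
    """
    if kind not in _TABLE_KINDS:
        raise ValidationError(f"unknown table kind {kind!r}")
    _, factor = _TABLE_KINDS[kind]
    df = _read_tabular(path)
    if df.empty:
        log.warning("table %s (%s) is empty", path, kind)
        return {}
    if df.shape[1] < 2:
        raise ValidationError(f"table {path}: need at least 2 columns")
    keys = df.iloc[:, 0].astype(str)
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise ValidationError(f"table {path}: duplicate keys {sorted(set(dup))}")
    out: dict[str, float] = {}
    for i, (key, raw) in enumerate(zip(keys, df.iloc[:, 1])):
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"table {path}: non-numeric value {raw!r} in data row {i + 1}"
            ) from None
        out[key] = val * factor
    return out


def read_kcat_provenance(path: str | Path) -> dict[str, str]:
    """Provenance column of a kcat table, if present (else empty)."""
    df = _read_tabular(path)
    if df.empty or df.shape[1] < 3:
        return {}
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 2].astype(str)))


def _read_tabular(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_table(mapping: dict[str, float], path: str | Path, columns=("key", "value")) -> None:
    """Write a keyed mapping as a 2-column TSV (deterministic key order)."""
    df = pd.DataFrame(sorted(mapping.items()), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def read_media(path: str | Path) -> dict[str, Medium]:
    """Read media from TSV with columns medium, exchange[, uptake_bound]."""
    df = _read_tabular(path)
    if df.empty:
        return {}
    if df.shape[1] < 2:
        raise ValidationError(f"media table {path}: need columns medium, exchange")
    media: dict[str, Medium] = {}
    opens: dict[str, set[str]] = {}
    caps: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        name = str(row.iloc[0])
        ex = str(row.iloc[1])
        opens.setdefault(name, set()).add(ex)
        if df.shape[1] >= 3 and pd.notna(row.iloc[2]):
            caps.setdefault(name, {})[ex] = float(row.iloc[2])
    for name in sorted(opens):
        media[name] = Medium(name, frozenset(opens[name]), caps.get(name, {}))
    return media
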