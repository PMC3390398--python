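"""Assembling turnover numbers and molecular weights.

Raw kcat measurements (from curated BRENDA/SABIO-RK exports) are
aggregated to one turnover number per reaction with explicit provenance:

1. mutant-enzyme measurements are discarded;
2. if measurements for the target organism exist, their median is used
   (``measured_self``);
3. otherwise the mean over other-species measurements (``other_species_mean``);
4. reactions still without a value get the median turnover number across
   all reactions resolved in steps 2-3 (``global_median_fill``).

Protein molecular weights are computed from amino-acid sequence using
average-isotope residue masses (bulk mass budgeting, not monoisotopic).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .enzyme import (
    GLOBAL_MEDIAN_FILL,
    MEASURED_SELF,
    OTHER_SPECIES_MEAN,
    EnzymeParams,
)
from .errors import ValidationError
from .model import MetabolicModel

#: average residue masses (Da) of the 20 standard amino acids, i.e. the
#: monomer mass minus one water; summing residues and adding one water
#: gives the average molecular weight of the peptide.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153
#: unknown residue ('X'): mean of the 20 standard residue masses
UNKNOWN_RESIDUE_MASS_DA = sum(RESIDUE_MASS_DA.values()) / len(RESIDUE_MASS_DA)


@dataclass(frozen=True)
class KcatRecord:
    """One raw turnover-number measurement (value in 1/s, file units)."""

    key: str                 # reaction id or EC number
    organism: str
    value: float             # 1/s
    mutant: bool = False

    def __post_init__(self):
        if self.value <= 0:
            raise ValidationError(f"kcat record for {self.key!r} must be > 0")


def assemble_kcats(
    records: list[KcatRecord],
    model: MetabolicModel,
    target_organism: str,
) -> tuple[dict[str, float], dict[str, str], dict[str, int]]:
    """Aggregate raw records into one kcat (1/h) per model reaction.

    Records are matched to reactions by reaction id or by EC number
    (via ``Reaction.ec_numbers``).  Returns (kcat in 1/h, provenance flag
    per reaction, counts per provenance class).  Duplicated measurements
    are kept as-is (no deduplication before the median/mean).
    """
    by_reaction: dict[str, list[KcatRecord]] = {r.id: [] for r in model.reactions}
    ec_index: dict[str, list[str]] = {}
    for r in model.reactions:
        for ec in r.ec_numbers:
            ec_index.setdefault(ec, []).append(r.id)
    for rec in records:
        if rec.mutant:
            continue
        if rec.key in by_reaction:
            by_reaction[rec.key].append(rec)
        for rid in ec_index.get(rec.key, ()):
            by_reaction[rid].append(rec)

    kcat: dict[str, float] = {}
    provenance: dict[str, str] = {}
    target = target_organism.lower()
    for r in model.reactions:
        if r.gpr is None:
            continue
        recs = by_reaction[r.id]
        self_vals = sorted(x.value for x in recs if x.organism.lower() == target)
        other_vals = sorted(x.value for x in recs if x.organism.lower() != target)
        if self_vals:
            kcat[r.id] = statistics.median(self_vals)
            provenance[r.id] = MEASURED_SELF
        elif other_vals:
            kcat[r.id] = statistics.fmean(other_vals)
            provenance[r.id] = OTHER_SPECIES_MEAN
    if not kcat:
        raise ValidationError(
            "no usable (non-mutant) kcat records matched any model reaction"
        )
    global_median = statistics.median(sorted(kcat.values()))
    for r in model.reactions:
        if r.gpr is not None and r.id not in kcat:
            kcat[r.id] = global_median
            provenance[r.id] = GLOBAL_MEDIAN_FILL
    counts = {
        flag: sum(1 for p in provenance.values() if p == flag)
        for flag in (MEASURED_SELF, OTHER_SPECIES_MEAN, GLOBAL_MEDIAN_FILL)
    }
    kcat_per_h = {rid: v * 3600.0 for rid, v in kcat.items()}
    return kcat_per_h, provenance, counts


def compute_mw(sequence: str) -> float:
    """Average molecular weight of a protein sequence in g/mmol (= kDa).

    Sums average residue masses plus one water; 'X' is tolerated with the
    mean residue mass.  Raises on empty input or an illegal character,
    naming its position.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    total = WATER_MASS_DA
    for i, aa in enumerate(sequence.upper()):
        if aa in RESIDUE_MASS_DA:
            total += RESIDUE_MASS_DA[aa]
        elif aa == "X":
            total += UNKNOWN_RESIDUE_MASS_DA
        else:
            raise ValidationError(
                f"illegal amino-acid character {aa!r} at position {i}"
            )
    return total / 1000.0


def mw_table_from_fasta(path) -> dict[str, float]:
    """Per-gene molecular weights (g/mmol) from a protein FASTA file.

    Record ids are taken as gene identifiers (text before the first
    whitespace in the header).
    """
    from Bio import SeqIO

    out: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA record id {rec.id!r}")
        out[rec.id] = compute_mw(str(rec.seq))
    return out


def read_kcat_records(path) -> list[KcatRecord]:
    """Read raw measurement records from TSV/CSV.

    Expected columns (by position): reaction id or EC number, organism,
    kcat value in 1/s, and optionally a mutant flag (true/false/1/0).
    """
    import pandas as pd

    from .io import _read_tabular

    df = _read_tabular(path)
    if df.empty:
        return []
    if df.shape[1] < 3:
        raise ValidationError(f"kcat record table {path}: need >= 3 columns")
    records = []
    for i, row in df.iterrows():
        try:
            value = float(row.iloc[2])
        except (TypeError, ValueError):
            raise ValidationError(
                f"kcat record table {path}: non-numeric value in data row {i + 1}"
            ) from None
        mutant = False
        if df.shape[1] >= 4 and pd.notna(row.iloc[3]):
            mutant = str(row.iloc[3]).strip().lower() in ("1", "true", "yes")
        records.append(
            KcatRecord(
                key=str(row.iloc[0]),
                organism=str(row.iloc[1]),
                value=value,
                mutant=mutant,
            )
        )
    return records


def restrict_to_self_measured(params: EnzymeParams) -> EnzymeParams:
    """Keep capacity rows only for reactions with own-organism kcats.

    Reactions whose kcat came from other species or the global median
    lose their capacity row (become uncapacitated), which reduces the
    enzyme-constrained model toward plain FBA as fewer reactions carry
    measured kinetics.
    """
    keep = {
        rid for rid, flag in params.provenance.items() if flag == MEASURED_SELF
    }
    dropped = set(params.kcat) - keep
    return EnzymeParams(
        kcat={rid: k for rid, k in params.kcat.items() if rid in keep},
        mw=dict(params.mw),
        capacity_C=params.capacity_C,
        provenance={rid: p for rid, p in params.provenance.items() if rid in keep},
        kcat_backward={
            rid: k for rid, k in params.kcat_backward.items() if rid in keep
        },
        isozyme_kcat={
            key: k for key, k in params.isozyme_kcat.items() if key[0] in keep
        },
        uncapacitated=set(params.uncapacitated) | dropped,
    )
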