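"""Octanol/water partition coefficients from solvation free energies.

The solvation free energy of a dye in an implicit solvent is the difference
between its total energy in solvent and in vacuum,

    dG_solv = E_solvated - E_vacuum,

and the octanol/water partition coefficient follows from the solvation
free-energy difference between the two solvents,

    log(P_o/w) = -(dG_octanol - dG_water) / (2.3 R T),

with R = 8.31 J/(mol K) and T = 273.15 K by convention here. A more positive
log(P_o/w) means a more hydrophobic dye. The factor 2.3 approximates ln 10
(2.3026); using the exact value changes log P by < 0.2% and is available via
``log_factor=math.log(10)``.

Energies enter in a single declared unit per table (kcal/mol by default, the
quantum-chemistry convention, or kJ/mol) and are converted to J/mol
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UnitMismatchError, ValidationError
from .geometry import CONSTANTS

_UNIT_TO_J_PER_MOL = {
    "kcal/mol": 4184.0,
    "kJ/mol": 1000.0,
    "J/mol": 1.0,
}

DEFAULT_LOG_FACTOR = 2.3


@dataclass(frozen=True)
class SolvationRecord:
    """Solvation free energy of one dye in one solvent."""

    dye_id: str
    E_solvated: float
    E_vacuum: float
    solvent: str          # "water" or "n-octanol"
    unit: str = "kcal/mol"

    @property
    def dG_solv(self) -> float:
        return self.E_solvated - self.E_vacuum


@dataclass(frozen=True)
class PartitionResult:
    """Octanol/water partitioning of one dye; energies in J/mol."""

    dye_id: str
    dG_octanol: float
    dG_water: float
    log_pow: float
    temperature: float


def solvation_free_energy(
    E_solvated: float, E_vacuum: float, unit: str = "kcal/mol", unit_vacuum: str | None = None
) -> float:
    """dG_solv = E_solvated - E_vacuum, in the declared unit.

    Both energies must share the unit; passing a different ``unit_vacuum``
    raises :class:`UnitMismatchError` rather than silently converting.
    """
    if unit not in _UNIT_TO_J_PER_MOL:
        raise ValidationError(f"unknown energy unit {unit!r}")
    if unit_vacuum is not None and unit_vacuum != unit:
        raise UnitMismatchError(
            f"solvated energy in {unit!r} but vacuum energy in {unit_vacuum!r}; "
            f"declare one unit per table"
        )
    return E_solvated - E_vacuum


def log_pow(
    dG_octanol: float,
    dG_water: float,
    T: float = CONSTANTS.default_temperature,
    log_factor: float = DEFAULT_LOG_FACTOR,
    gas_constant: float = CONSTANTS.gas_constant,
) -> float:
    """log10 octanol/water partition coefficient.

    Parameters
    ----------
    dG_octanol, dG_water : float
        Solvation free energies in J/mol (normalise units first).
    T : float
        Temperature in K, default 273.15.
    log_factor : float
        2.3 by default; ``math.log(10)`` for the exact conversion.
    """
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return -(dG_octanol - dG_water) / (log_factor * gas_constant * T)


def partition_from_record_pair(
    dye_id: str,
    water: SolvationRecord,
    octanol: SolvationRecord,
    T: float = CONSTANTS.default_temperature,
    log_factor: float = DEFAULT_LOG_FACTOR,
) -> PartitionResult:
    if water.unit != octanol.unit:
        raise UnitMismatchError(
            f"dye {dye_id!r}: water table in {water.unit!r}, octanol table in "
            f"{octanol.unit!r}"
        )
    scale = _UNIT_TO_J_PER_MOL[water.unit]
    dGw = water.dG_solv * scale
    dGo = octanol.dG_solv * scale
    return PartitionResult(
        dye_id=dye_id,
        dG_octanol=dGo,
        dG_water=dGw,
        log_pow=log_pow(dGo, dGw, T=T, log_factor=log_factor),
        temperature=T,
    )


def rank_hydrophobicity(records: list[PartitionResult]) -> list[PartitionResult]:
    """Most hydrophobic (largest log P) first; ties broken by dye_id."""
    if not records:
        raise ValidationError("no partition records to rank")
    return sorted(records, key=lambda r: (-r.log_pow, r.dye_id))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

#: expected columns; separate vacuum references for the two solvent workflows
TABLE_COLUMNS = [
    "dye_id",
    "E_solv_water",
    "E_vac_water",
    "E_solv_octanol",
    "E_vac_octanol",
]


def partition_table(
    df: pd.DataFrame,
    unit: str = "kcal/mol",
    T: float = CONSTANTS.default_temperature,
    log_factor: float = DEFAULT_LOG_FACTOR,
) -> pd.DataFrame:
    """Compute ranked log(P_o/w) for a solvation-energy table.

    The table either carries raw energies (``E_solv_*`` / ``E_vac_*``
    columns) or direct ``dG_water`` / ``dG_octanol`` columns, in one declared
    unit. Returns a DataFrame sorted most-hydrophobic-first.
    """
    if unit not in _UNIT_TO_J_PER_MOL:
        raise ValidationError(f"unknown energy unit {unit!r}")
    if "dye_id" not in df.columns:
        raise ValidationError("solvation table must have a dye_id column")
    scale = _UNIT_TO_J_PER_MOL[unit]
    if {"dG_water", "dG_octanol"}.issubset(df.columns):
        dGw = df["dG_water"].to_numpy(float) * scale
        dGo = df["dG_octanol"].to_numpy(float) * scale
    elif set(TABLE_COLUMNS).issubset(df.columns):
        dGw = (df["E_solv_water"] - df["E_vac_water"]).to_numpy(float) * scale
        dGo = (df["E_solv_octanol"] - df["E_vac_octanol"]).to_numpy(float) * scale
    else:
        raise ValidationError(
            f"solvation table needs either dG_water/dG_octanol or "
            f"{TABLE_COLUMNS[1:]} columns"
        )
    results = [
        PartitionResult(
            dye_id=str(d),
            dG_octanol=o,
            dG_water=w,
            log_pow=log_pow(o, w, T=T, log_factor=log_factor),
            temperature=T,
        )
        for d, o, w in zip(df["dye_id"], dGo, dGw)
    ]
    ranked = rank_hydrophobicity(results)
    return pd.DataFrame(
        {
            "dye_id": [r.dye_id for r in ranked],
            "dG_water_J_per_mol": [r.dG_water for r in ranked],
            "dG_octanol_J_per_mol": [r.dG_octanol for r in ranked],
            "log_pow": [r.log_pow for r in ranked],
        }
    )
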