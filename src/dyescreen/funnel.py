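"""Screening funnel: join ML-predicted epsilon with dipole moments and
hydrophobicity, and flag promising dye candidates.

The funnel ranks prediction-only molecules by regressor-predicted epsilon
and, where transition dipole magnitudes (TD-DFT) and solvation-energy tables
are supplied for the candidates, annotates each with:

* ``epsilon_above_threshold`` — predicted epsilon >= 150,000 M^-1 cm^-1;
* ``mu_comparable`` — |mu - mu_ref| / mu_ref <= mu_tol (default: within 50%
  of the Cy5 reference, mu_ref = 15.35 D);
* ``hydrophobic`` — log(P_o/w) > 0 (negative values flag hydrophilic dyes);
* ``promising`` — all of the above that could be evaluated are true.

Missing join keys degrade gracefully: the candidate stays ranked, the flags
that need the missing quantity are left null, and a warning is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import CONSTANTS
from .hydrophobicity import DEFAULT_LOG_FACTOR, partition_table
from .screening import ModelReport, predict_and_rank

logger = logging.getLogger(__name__)

MU_REFERENCE_DEBYE = 15.35   # Cy5
MU_TOLERANCE = 0.5           # "comparable" = within 50% of the reference


def run_funnel(
    molecules: pd.DataFrame,
    report: ModelReport,
    top_n: int = 100,
    mu_table: pd.DataFrame | None = None,
    solvation_table: pd.DataFrame | None = None,
    mu_ref: float = MU_REFERENCE_DEBYE,
    mu_tol: float = MU_TOLERANCE,
    solvation_unit: str = "kcal/mol",
    T: float = CONSTANTS.default_temperature,
    log_factor: float = DEFAULT_LOG_FACTOR,
) -> pd.DataFrame:
    """Rank candidates and flag them by the screening criteria.

    Parameters
    ----------
    molecules : DataFrame
        Prediction-only table with molecule_id and smiles columns.
    report : ModelReport
        A trained regressor report.
    mu_table : DataFrame, optional
        Columns molecule_id, mu_debye (TD-DFT transition dipole magnitudes).
    solvation_table : DataFrame, optional
        Solvation energies accepted by
        :func:`dyescreen.hydrophobicity.partition_table`, with dye_id values
        matching molecule ids.
    """
    if mu_ref <= 0:
        raise ValidationError("mu_ref must be positive")
    ranked = predict_and_rank(report, molecules, top_n=top_n)
    out = ranked.copy()
    out["epsilon_above_threshold"] = ~out["below_threshold"]

    if mu_table is not None:
        mu = mu_table.set_index(mu_table["molecule_id"].astype(str))["mu_debye"]
        out["mu_debye"] = out["molecule_id"].map(mu)
        out["mu_comparable"] = (
            (out["mu_debye"] - mu_ref).abs() / mu_ref <= mu_tol
        ).where(out["mu_debye"].notna())
        n_missing = int(out["mu_debye"].isna().sum())
        if n_missing:
            logger.warning("%d candidates missing from the mu table", n_missing)
    else:
        out["mu_debye"] = np.nan
        out["mu_comparable"] = pd.Series([None] * len(out), dtype=object)

    if solvation_table is not None:
        logp = partition_table(
            solvation_table, unit=solvation_unit, T=T, log_factor=log_factor
        ).set_index("dye_id")["log_pow"]
        out["log_pow"] = out["molecule_id"].map(logp)
        out["hydrophobic"] = (out["log_pow"] > 0).where(out["log_pow"].notna())
        n_missing = int(out["log_pow"].isna().sum())
        if n_missing:
            logger.warning(
                "%d candidates missing from the solvation table", n_missing
            )
    else:
        out["log_pow"] = np.nan
        out["hydrophobic"] = pd.Series([None] * len(out), dtype=object)

    def _promising(row) -> object:
        checks = [row["epsilon_above_threshold"]]
        for key in ("mu_comparable", "hydrophobic"):
            if pd.notna(row[key]):
                checks.append(bool(row[key]))
        return all(checks)

    out["promising"] = out.apply(_promising, axis=1)
    out["annotation"] = ""   # free-text field for chemist judgment
    return out
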