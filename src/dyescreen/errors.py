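"""Exception hierarchy for dyescreen.

All dyescreen errors derive from :class:`DyescreenError` so callers can catch
the whole family; validation-style errors also derive from ``ValueError``.
"""


class DyescreenError(Exception):
    """Base class for all dyescreen errors."""


class ValidationError(DyescreenError, ValueError):
    """Invalid argument or precondition violation."""


class DegenerateGeometryError(ValidationError):
    """Zero-length dipole or coincident centers."""


class SingularityError(ValidationError):
    """Two interaction endpoints overlap; the Coulomb kernel diverges."""


class UnitMismatchError(ValidationError):
    """Energies combined across different declared units."""


class SelectionError(ValidationError):
    """An atom-selection spec matched no atoms or missing atoms."""


class PeriodicImageError(DyescreenError):
    """A selected atom group spans more than a molecule plausibly can;
    the trajectory likely needs re-imaging (molecules made whole) first."""


class EmptyAnalysisError(ValidationError):
    """No frames remain after the requested time window was applied."""


class SmilesParseError(DyescreenError):
    """A SMILES string could not be parsed; carries the molecule id."""

    def __init__(self, molecule_id, smiles):
        self.molecule_id = molecule_id
        self.smiles = smiles
        super().__init__(f"unparseable SMILES for molecule {molecule_id!r}: {smiles!r}")


class TrainingError(DyescreenError):
    """Model training impossible (e.g. single-class development set)."""
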