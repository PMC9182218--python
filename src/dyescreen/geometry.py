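"""Core value types and physical constants for extended-dipole geometry.

Conventions
-----------
All external coordinates are in nanometres, transition dipole magnitudes in
Debye, times in picoseconds, energies in meV. Conversions to SI happen at a
single boundary (the constants below); everything downstream works in SI and
converts back on output.

A dye's transition dipole is represented by its two endpoints ``r_end`` and
``s_end`` along the dye's long axis plus the scalar magnitude ``mu``. The
axis direction is taken from ``r_end`` toward ``s_end`` as supplied; no sign
convention is imposed, so orientation factors and couplings are reported both
signed and as absolute values, with the absolute value being the user-facing
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _sc

from .errors import DegenerateGeometryError, ValidationError

#: distances below this (nm) are treated as degenerate geometry
DEGENERACY_TOL_NM = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the physical constants used throughout.

    Attributes
    ----------
    vacuum_permittivity : float
        epsilon_0 in C^2 J^-1 m^-1 (CODATA, 8.85418781e-12).
    debye_to_Cm : float
        1 Debye in C·m (3.33564095e-30, = 1e-21 / c).
    joule_to_meV : float
        meV per joule (6.24150907e+21).
    gas_constant : float
        R in J mol^-1 K^-1. Default 8.31, the rounded value entering the
        partition-coefficient formula; the CODATA value is 8.314463.
    default_temperature : float
        K. The partitioning formula is conventionally evaluated at 273.15 K.
    refractive_index_default : float
        Screening medium for the coupling prefactor; water, n = 1.33.
    """

    vacuum_permittivity: float = _sc.epsilon_0            # 8.8541878128e-12
    debye_to_Cm: float = 1e-21 / _sc.c                    # 3.3356409519e-30
    joule_to_meV: float = 1.0 / (_sc.e * 1e-3)            # 6.2415090744e+21
    gas_constant: float = 8.31
    default_temperature: float = 273.15
    refractive_index_default: float = 1.33


CONSTANTS = PhysicalConstants()


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} must be finite, got {v}")
    return v


@dataclass(frozen=True)
class ExtendedDipole:
    """One dye's transition dipole as two endpoints plus a magnitude.

    Parameters
    ----------
    r_end, s_end : (3,) array, nm
        Endpoints along the dye's long axis (centers of the terminal aryl
        groups for real cyanine dyes).
    mu : float, Debye
        Transition dipole magnitude; mu = 0 is allowed (dark dye).
    """

    r_end: np.ndarray
    s_end: np.ndarray
    mu: float

    def __post_init__(self):
        object.__setattr__(self, "r_end", _as_vec3(self.r_end, "r_end"))
        object.__setattr__(self, "s_end", _as_vec3(self.s_end, "s_end"))
        if not np.isfinite(self.mu):
            raise ValidationError(f"mu must be finite, got {self.mu}")
        if self.mu < 0:
            raise ValidationError(f"mu must be >= 0 Debye, got {self.mu}")
        if self.length < DEGENERACY_TOL_NM:
            raise DegenerateGeometryError(
                f"dipole endpoints coincide (|r-s| = {self.length:.3g} nm "
                f"< {DEGENERACY_TOL_NM} nm)"
            )

    @property
    def length(self) -> float:
        """Dye length l = |r_end - s_end| in nm."""
        return float(np.linalg.norm(self.s_end - self.r_end))

    @property
    def center(self) -> np.ndarray:
        """Midpoint between the endpoints, nm."""
        return 0.5 * (self.r_end + self.s_end)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from r_end toward s_end."""
        return (self.s_end - self.r_end) / self.length


def make_dipole(r_end, s_end, mu: float) -> ExtendedDipole:
    """Construct and validate an :class:`ExtendedDipole`.

    Raises
    ------
    DegenerateGeometryError
        If the endpoints are closer than 1e-6 nm.
    ValidationError
        If mu < 0 or any coordinate is non-finite.
    """
    return ExtendedDipole(r_end=r_end, s_end=s_end, mu=float(mu))


@dataclass(frozen=True)
class DimerFrame:
    """Two extended dipoles at one time point.

    The center-to-center vector runs from dye m's center toward dye n's.
    """

    dye_m: ExtendedDipole
    dye_n: ExtendedDipole
    time: float = 0.0  # ps

    def __post_init__(self):
        sep = self.dye_n.center - self.dye_m.center
        if float(np.linalg.norm(sep)) < DEGENERACY_TOL_NM:
            raise DegenerateGeometryError(
                "dye centers coincide; center-to-center distance undefined"
            )


def center_distance(frame: DimerFrame) -> tuple[float, np.ndarray]:
    """Center-to-center distance R (nm) and unit vector R_hat (m -> n)."""
    sep = frame.dye_n.center - frame.dye_m.center
    R = float(np.linalg.norm(sep))
    if R < DEGENERACY_TOL_NM:  # unreachable for validated frames; kept as a guard
        raise DegenerateGeometryError("coincident dye centers")
    return R, sep / R
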