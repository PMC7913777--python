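"""Composition bookkeeping and hydrodynamic conversions.

Molar masses and partial specific volumes of protein complexes are obtained
by additivity from their components; buoyant molar masses ``M(1 - vbar*rho)``
feed the sedimentation-equilibrium exponentials, the Svedberg relation
``D = s R T / M(1 - vbar*rho)`` supplies diffusion coefficients for the Lamm
solver, and observed sedimentation coefficients are corrected to standard
conditions (water, 20 degC).

External units follow AUC practice: masses in kDa, partial specific volumes in
ml/g, sedimentation coefficients in Svedberg (1e-13 s), densities in g/ml,
viscosities in cP, diffusion coefficients in cm^2/s.  Internally SI is used
(kg/mol, s, Pa*s, kg/m^3, m^2/s); the conversion layer lives in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "RHO_20W",
    "ETA_20W",
    "SVEDBERG",
    "Species",
    "BufferState",
    "vbar_additive",
    "total_molar_mass",
    "buoyant_factor",
    "diffusion_from_s",
    "s20w_correct",
    "glycerol_buffer_properties",
]

# ---------------------------------------------------------------------------
# Physical constants and unit conversions (one place, round-trip tested)
# ---------------------------------------------------------------------------

GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1

#: Reference water constants used for s20,w correction.
RHO_20W = 0.99823  # g/ml, water at 20 degC
ETA_20W = 1.002  # cP, water at 20 degC

SVEDBERG = 1e-13  # s

_KDA_TO_KG_PER_MOL = 1.0  # 1 kDa = 1 kg/mol (numeric identity)
_ML_PER_G_TO_M3_PER_KG = 1e-3
_G_PER_ML_TO_KG_PER_M3 = 1e3
_CP_TO_PA_S = 1e-3
_M2_TO_CM2 = 1e4


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """One sedimenting, absorbing molecular entity.

    Parameters
    ----------
    name : str
        Label, e.g. ``"RecR4O2"``.
    molar_mass : float
        Molar mass in kDa.
    vbar : float
        Partial specific volume in ml/g; must lie in (0.5, 1.0).
    s_buffer : float
        Sedimentation coefficient in the working buffer, Svedberg.
    extinction : float
        Molar extinction coefficient at the stated wavelength, M^-1 cm^-1.
    monomer_composition : tuple of (label, copies), optional
        If given, consistency of ``molar_mass`` with the composition is the
        caller's responsibility via :func:`total_molar_mass`.
    """

    name: str
    molar_mass: float
    vbar: float
    s_buffer: float = 0.0
    extinction: float = 0.0
    monomer_composition: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InvalidInputError(f"{self.name}: molar_mass must be > 0")
        if not 0.5 < self.vbar < 1.0:
            raise InvalidInputError(f"{self.name}: vbar must lie in (0.5, 1.0) ml/g")
        if self.extinction < 0:
            raise InvalidInputError(f"{self.name}: extinction must be >= 0")

    def check_composition(self, monomer_masses: dict[str, float], tol: float = 0.05) -> None:
        """Verify molar_mass equals the composition sum within ``tol`` kDa."""
        if not self.monomer_composition:
            return
        total = sum(n * monomer_masses[label] for label, n in self.monomer_composition)
        if abs(total - self.molar_mass) > tol:
            raise InvalidInputError(
                f"{self.name}: molar_mass {self.molar_mass} kDa differs from "
                f"composition sum {total} kDa by more than {tol} kDa"
            )


@dataclass(frozen=True)
class BufferState:
    """Solvent condition: density (g/ml), viscosity (cP), temperature (K), pH."""

    density: float
    viscosity: float
    temperature: float = 298.15
    pH: float = 8.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidInputError("density must be > 0")
        if self.viscosity <= 0:
            raise InvalidInputError("viscosity must be > 0")
        if not 273.0 < self.temperature < 373.0:
            raise InvalidInputError("temperature must lie in (273, 373) K")
        if not 0.0 < self.pH < 14.0:
            raise InvalidInputError("pH must lie in (0, 14)")

    @property
    def proton_concentration(self) -> float:
        """[H+] in M, 10**(-pH)."""
        return 10.0 ** (-self.pH)


#: Water at 20 degC, the s20,w reference state.
WATER_20C = BufferState(density=RHO_20W, viscosity=ETA_20W, temperature=293.15, pH=7.0, label="water, 20C")


# ---------------------------------------------------------------------------
# Composition arithmetic
# ---------------------------------------------------------------------------


def vbar_additive(components: Sequence[tuple[float, float, float]]) -> float:
    """Mass-weighted partial specific volume of a complex.

    vbar = sum(n_i M_i vbar_i) / sum(n_i M_i) over components given as
    ``(moles, molar_mass_kDa, vbar_ml_g)``.
    """
    if len(components) == 0:
        raise InvalidInputError("vbar_additive: empty component list")
    num = 0.0
    den = 0.0
    for moles, mass, vbar in components:
        if moles <= 0 or mass <= 0:
            raise InvalidInputError("vbar_additive: moles and masses must be > 0")
        if not 0.5 < vbar < 1.0:
            raise InvalidInputError("vbar_additive: vbar must lie in (0.5, 1.0)")
        num += moles * mass * vbar
        den += moles * mass
    return num / den


def total_molar_mass(components: Sequence[tuple[float, float]]) -> float:
    """Total molar mass sum(n_i M_i) in kDa of ``(moles, molar_mass_kDa)`` pairs."""
    if len(components) == 0:
        raise InvalidInputError("total_molar_mass: empty component list")
    total = 0.0
    for moles, mass in components:
        if moles <= 0 or mass <= 0:
            raise InvalidInputError("total_molar_mass: moles and masses must be > 0")
        total += moles * mass
    return total


# ---------------------------------------------------------------------------
# Buoyancy, diffusion, standard-condition correction
# ---------------------------------------------------------------------------


def buoyant_factor(molar_mass: float, vbar: float, buffer: BufferState) -> float:
    """Buoyant molar mass M(1 - vbar*rho) in kDa.

    Zero at neutral buoyancy (vbar*rho = 1), strictly decreasing in density.
    """
    if molar_mass <= 0:
        raise InvalidInputError("buoyant_factor: molar_mass must be > 0")
    if not 0.5 < vbar < 1.0:
        raise InvalidInputError("buoyant_factor: vbar must lie in (0.5, 1.0)")
    return molar_mass * (1.0 - vbar * buffer.density)


def diffusion_from_s(s: float, molar_mass: float, vbar: float, buffer: BufferState) -> float:
    """Diffusion coefficient (cm^2/s) from the Svedberg relation.

    D = s R T / (M (1 - vbar rho)).  ``s`` in Svedberg.  Undefined (error) at
    neutral or negative buoyancy.
    """
    mb = buoyant_factor(molar_mass, vbar, buffer)  # kDa = kg/mol
    if mb <= 0:
        raise InvalidInputError("diffusion_from_s: requires positive buoyant molar mass")
    d_si = (s * SVEDBERG) * GAS_CONSTANT * buffer.temperature / (mb * _KDA_TO_KG_PER_MOL)
    return d_si * _M2_TO_CM2


def s20w_correct(s_obs: float, buffer: BufferState, vbar: float) -> float:
    """Correct an observed sedimentation coefficient to water at 20 degC.

    s20,w = s_obs * (eta_buffer/eta_20w) * (1 - vbar rho)_20w / (1 - vbar rho)_buffer
    """
    num = 1.0 - vbar * RHO_20W
    den = 1.0 - vbar * buffer.density
    if num <= 0 or den <= 0:
        raise InvalidInputError("s20w_correct: neutral/negative buoyancy in reference or buffer")
    return s_obs * (buffer.viscosity / ETA_20W) * num / den


def s_buffer_from_s20w(s20w: float, buffer: BufferState, vbar: float) -> float:
    """Inverse of :func:`s20w_correct` (exact round trip)."""
    num = 1.0 - vbar * RHO_20W
    den = 1.0 - vbar * buffer.density
    if num <= 0 or den <= 0:
        raise InvalidInputError("s_buffer_from_s20w: neutral/negative buoyancy")
    return s20w * (ETA_20W / buffer.viscosity) * den / num


# ---------------------------------------------------------------------------
# Glycerol-water solvent properties
# ---------------------------------------------------------------------------
# Grid compiled from standard published glycerol-water tables (density from
# CRC-style wt% tables, viscosity from Segur-Oberstar-style measurements),
# converted to % v/v with rho_glycerol = 1.261 g/ml.  Bilinear interpolation
# inside the grid; out-of-range requests raise, never extrapolate.

_GLY_VV = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])  # % v/v
_GLY_T = np.array([288.15, 293.15, 298.15, 303.15, 308.15, 313.15])  # K

_GLY_RHO = np.array(
    [  # g/ml, rows = vv, cols = T
        [0.99913, 0.99823, 0.99705, 0.99565, 0.99403, 0.99222],
        [1.02990, 1.02810, 1.02640, 1.02460, 1.02290, 1.02110],
        [1.05920, 1.05720, 1.05520, 1.05320, 1.05120, 1.04920],
        [1.08860, 1.08630, 1.08410, 1.08180, 1.07960, 1.07730],
        [1.11720, 1.11470, 1.11220, 1.10970, 1.10720, 1.10470],
        [1.14480, 1.14230, 1.13980, 1.13730, 1.13480, 1.13230],
    ]
)

_GLY_ETA = np.array(
    [  # cP
        [1.139, 1.002, 0.890, 0.798, 0.719, 0.653],
        [1.572, 1.383, 1.228, 1.101, 0.992, 0.901],
        [2.210, 1.944, 1.727, 1.548, 1.395, 1.267],
        [3.383, 2.976, 2.643, 2.370, 2.135, 1.939],
        [5.410, 4.760, 4.228, 3.790, 3.415, 3.102],
        [9.226, 8.116, 7.209, 6.464, 5.824, 5.289],
    ]
)

#: Density increment per molar NaCl, g ml^-1 M^-1 (linear, dilute regime).
NACL_DENSITY_INCREMENT = 0.0414


def glycerol_buffer_properties(
    glycerol_vv: float, temperature: float, nacl_molar: float = 0.0
) -> tuple[float, float]:
    """Density (g/ml) and viscosity (cP) of a glycerol-water buffer.

    Bilinear interpolation of an embedded published 0-50 % v/v grid over
    288-313 K.  Salt contributes a linear molar density increment; its
    viscosity contribution is neglected (small at <= 200 mM).
    """
    if not 0.0 <= glycerol_vv <= 50.0:
        raise InvalidInputError("glycerol_buffer_properties: glycerol_vv outside [0, 50] % v/v")
    if not _GLY_T[0] <= temperature <= _GLY_T[-1]:
        raise InvalidInputError("glycerol_buffer_properties: temperature outside [288.15, 313.15] K")
    if nacl_molar < 0:
        raise InvalidInputError("glycerol_buffer_properties: nacl_molar must be >= 0")

    iv = int(np.clip(np.searchsorted(_GLY_VV, glycerol_vv) - 1, 0, len(_GLY_VV) - 2))
    it = int(np.clip(np.searchsorted(_GLY_T, temperature) - 1, 0, len(_GLY_T) - 2))
    fv = (glycerol_vv - _GLY_VV[iv]) / (_GLY_VV[iv + 1] - _GLY_VV[iv])
    ft = (temperature - _GLY_T[it]) / (_GLY_T[it + 1] - _GLY_T[it])

    def bilinear(grid: np.ndarray) -> float:
        return float(
            grid[iv, it] * (1 - fv) * (1 - ft)
            + grid[iv + 1, it] * fv * (1 - ft)
            + grid[iv, it + 1] * (1 - fv) * ft
            + grid[iv + 1, it + 1] * fv * ft
        )

    rho = bilinear(_GLY_RHO) + NACL_DENSITY_INCREMENT * nacl_molar
    eta = bilinear(_GLY_ETA)
    return rho, eta
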