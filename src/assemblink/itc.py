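"""Isothermal titration calorimetry: n-identical-independent-site isotherms.

The cumulative heat after the i-th injection for ligand X binding to n
identical independent sites on macromolecule M is

    Q_i = V0 * dH * M_tot * n K x / (1 + K x)

with the free ligand concentration x the positive root of

    X_tot = x + n K x / (1 + K x) * M_tot.

Measured data are differential (per-injection) heats; conversion from
cumulative heats includes the heat carried out of an overflow cell by the
displaced volume.  Cell concentrations after each injection follow the
standard displacement bookkeeping for an overflow cell with instantaneous
mixing: both solutes are diluted by (1 - dV/2V0)/(1 + dV/2V0) per injection
and the syringe delivers X_syr * dV/V0 / (1 + dV/2V0) of new ligand.

Units: volumes in ml (cell) and ul (injections), concentrations M,
K in M^-1, dH in kcal/mol, heats in ucal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .hydro import InvalidInputError

__all__ = [
    "ITCModel",
    "Titration",
    "free_ligand",
    "total_heat",
    "differential_heats",
    "injection_concentrations",
    "predict_differential_heats",
    "fit_itc",
]

KCAL_TO_UCAL = 1e9


@dataclass(frozen=True)
class ITCModel:
    """Binding model: n sites per macromolecule, K_obs (M^-1), dH_obs (kcal/mol)."""

    n: float
    K_obs: float  # M^-1
    dH_obs: float  # kcal/mol
    V0: float = 1.4  # ml, calorimetric cell volume

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InvalidInputError("ITCModel: n must be > 0")
        if self.K_obs < 0:
            raise InvalidInputError("ITCModel: K_obs must be >= 0")
        if self.V0 <= 0:
            raise InvalidInputError("ITCModel: V0 must be > 0")


@dataclass
class Titration:
    """An injection schedule with measured per-injection heats."""

    injection_volumes: np.ndarray  # ul
    syringe_conc: float  # M, ligand in syringe
    cell_conc: float  # M, macromolecule initially in cell
    heats: Optional[np.ndarray] = None  # ucal per injection
    blank_heats: Optional[np.ndarray] = None  # ucal per injection
    V0: float = 1.4  # ml

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if np.any(self.injection_volumes <= 0):
            raise InvalidInputError("Titration: injection volumes must be > 0")
        if self.syringe_conc < 0 or self.cell_conc < 0:
            raise InvalidInputError("Titration: concentrations must be >= 0")
        for name in ("heats", "blank_heats"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.injection_volumes.shape:
                    raise InvalidInputError(f"Titration: {name} misaligned with injections")
                setattr(self, name, v)

    @property
    def corrected_heats(self) -> np.ndarray:
        if self.heats is None:
            raise InvalidInputError("Titration: no measured heats")
        if self.blank_heats is None:
            return self.heats
        return self.heats - self.blank_heats


def free_ligand(X_tot: float, M_tot: float, n: float, K: float) -> tuple[float, float]:
    """Free ligand x and site occupancy Kx/(1+Kx) for n identical sites.

    Solves the binding quadratic K x^2 + (1 + n K M_tot - K X_tot) x - X_tot = 0
    for its unique positive root (numerically stable form).
    """
    if X_tot < 0 or M_tot < 0 or n <= 0 or K < 0:
        raise InvalidInputError("free_ligand: nonnegative totals, n > 0, K >= 0 required")
    if K == 0.0 or M_tot == 0.0:
        return float(X_tot), 0.0 if K == 0.0 else K * X_tot / (1.0 + K * X_tot)
    b = 1.0 + n * K * M_tot - K * X_tot
    disc = b * b + 4.0 * K * X_tot
    # stable root: x = (-b + sqrt(disc)) / 2K = 2 X_tot / (b + sqrt(disc))
    x = 2.0 * X_tot / (b + np.sqrt(disc))
    occ = K * x / (1.0 + K * x)
    return float(x), float(occ)


def total_heat(X_tot: float, M_tot: float, model: ITCModel) -> float:
    """Cumulative heat content of the cell (ucal) at total concentrations given.

    Zero at X_tot = 0; saturates at V0 * dH * n * M_tot as X_tot -> infinity.
    """
    if X_tot == 0.0:
        return 0.0
    _, occ = free_ligand(X_tot, M_tot, model.n, model.K_obs)
    q_kcal = (model.V0 * 1e-3) * model.dH_obs * M_tot * model.n * occ  # kcal
    return float(q_kcal * KCAL_TO_UCAL)


def differential_heats(
    Q_tot: Sequence[float], injection_volumes: Sequence[float], V0: float
) -> np.ndarray:
    """Convert cumulative heats to per-injection heats with displacement correction.

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1})/2, the second term being
    the heat content of the displaced overflow volume.  Volumes: dV in ul,
    V0 in ml.
    """
    Q = np.asarray(Q_tot, dtype=float)
    dV = np.asarray(injection_volumes, dtype=float) * 1e-3  # ul -> ml
    if Q.shape != dV.shape:
        raise InvalidInputError("differential_heats: sequences misaligned")
    Qprev = np.concatenate([[0.0], Q[:-1]])
    return Q - Qprev + (dV / V0) * (Q + Qprev) / 2.0


def injection_concentrations(titration: Titration) -> tuple[np.ndarray, np.ndarray]:
    """Cell (X_tot, M_tot) after each injection under displacement dilution."""
    dV = titration.injection_volumes * 1e-3  # ml
    V0 = titration.V0
    X = np.empty(dV.size)
    M = np.empty(dV.size)
    x_prev = 0.0
    m_prev = titration.cell_conc
    for i, dv in enumerate(dV):
        f = (1.0 - dv / (2.0 * V0)) / (1.0 + dv / (2.0 * V0))
        x_prev = x_prev * f + titration.syringe_conc * (dv / V0) / (1.0 + dv / (2.0 * V0))
        m_prev = m_prev * f
        X[i] = x_prev
        M[i] = m_prev
    return X, M


def predict_differential_heats(titration: Titration, model: ITCModel) -> np.ndarray:
    """Forward model: per-injection heats (ucal) for a titration schedule."""
    X, M = injection_concentrations(titration)
    Q = np.array([total_heat(x, m, model) for x, m in zip(X, M)])
    return differential_heats(Q, titration.injection_volumes, model.V0)


def fit_itc(
    titration: Titration,
    x0: Optional[ITCModel] = None,
    fix_n: Optional[float] = None,
) -> tuple[ITCModel, dict[str, float]]:
    """NLLS fit of (n, K, dH) to blank-corrected differential heats.

    Returns the fitted model and a dict of standard errors plus diagnostics
    (c-value = K * M_tot * n; warnings for c outside [1, 1000] or
    non-convergence).
    """
    y = titration.corrected_heats
    if y.size < 8:
        raise InvalidInputError("fit_itc: need >= 8 injections")
    V0 = titration.V0

    if x0 is None:
        # crude guesses: saturation heat ~ running sum, K from schedule midpoint
        q_sum = float(np.sum(y))
        dh0 = q_sum / max(titration.cell_conc * V0 * 1e-3 * KCAL_TO_UCAL, 1e-30)
        dh0 = dh0 if abs(dh0) > 1e-3 else -1.0
        x0 = ITCModel(n=1.0, K_obs=1e6, dH_obs=dh0, V0=V0)

    fit_n = fix_n is None

    def make_model(x):
        if fit_n:
            n, logK, dh = x
        else:
            n = fix_n
            logK, dh = x
        return ITCModel(n=float(n), K_obs=10.0 ** float(logK), dH_obs=float(dh), V0=V0)

    def residuals(x):
        return predict_differential_heats(titration, make_model(x)) - y

    p0 = [np.log10(max(x0.K_obs, 1.0)), x0.dH_obs]
    lb, ub = [-2.0, -np.inf], [14.0, np.inf]
    if fit_n:
        p0 = [x0.n] + p0
        lb, ub = [0.05] + lb, [20.0] + ub
    res = least_squares(residuals, np.asarray(p0), bounds=(lb, ub), method="trf", x_scale="jac")
    model = make_model(res.x)

    ndof = max(y.size - res.x.size, 1)
    s2 = 2.0 * res.cost / ndof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        err = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        err = np.full(res.x.size, np.nan)
    k = 0
    diag: dict[str, float] = {}
    if fit_n:
        diag["n"] = float(err[k])
        k += 1
    diag["K_obs"] = float(model.K_obs * np.log(10.0) * err[k])
    diag["dH_obs"] = float(err[k + 1])
    diag["rmsd_ucal"] = float(np.sqrt(np.mean(residuals(res.x) ** 2)))
    diag["c_value"] = float(model.K_obs * titration.cell_conc * model.n)
    diag["converged"] = float(res.success)
    diag["low_information"] = float(not (1.0 <= diag["c_value"] <= 1000.0))
    return model, diag
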