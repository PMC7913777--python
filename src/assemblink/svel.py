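"""Reacting-system sedimentation velocity: speciation, Lamm solver, c(s).

The reaction network couples a dimer-tetramer self-association of RecR with
step-wise binding of up to two RecO molecules to the tetramer:

    2 R2 <-> R4          L_obs = [R4]/[R2]^2
    R2 + O <-> R2O       K2
    R4 + O <-> R4O       K3
    R4O + O <-> R4O2     K4

Forward rate constants are K * k_off for each reaction.  Sedimentation and
diffusion in the sector-shaped cell follow the Lamm equation

    dc_i/dt = (1/r) d/dr [ r ( D_i dc_i/dr - s_i w^2 r^2 c_i ) ] + f_i(c)

with zero net flux at meniscus and bottom.  The solver uses a conservative
finite-volume radial grid, Crank-Nicolson transport (upwind advection,
central diffusion) and Strang-split reactions integrated by a damped Newton
backward-Euler substep, which preserves both conservation laws to machine
precision and tolerates stiff on-rates.

A simplified c(s)-style analysis fits scans to a nonnegative superposition of
single-species Lamm solutions on an s grid, with second-difference Tikhonov
smoothing; diffusion coefficients on the grid follow the standard
frictional-ratio scaling D(s).  A model-free transport (second-moment) method
provides an independent weight-average s from the same scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq, nnls

from .hydro import (
    GAS_CONSTANT,
    SVEDBERG,
    BufferState,
    InvalidInputError,
    Species,
    diffusion_from_s,
)

__all__ = [
    "SPECIES_ORDER",
    "ReactionNetwork",
    "CellGeometry",
    "SVScanSet",
    "CsDistribution",
    "default_network",
    "equilibrium_composition",
    "reaction_fluxes",
    "simulate_lamm",
    "add_noise",
    "sector_integral",
    "conserved_totals",
    "frictional_ratio_equivalent",
    "fit_cs",
    "weight_average_s",
    "transport_sw",
]

SPECIES_ORDER = ("O", "R2", "R4", "R2O", "R4O", "R4O2")

_KB = 1.380649e-23  # J/K

#: monomers of (O, R) in each species, for the two conservation laws
_O_CONTENT = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 2.0])
_R_CONTENT = np.array([0.0, 2.0, 4.0, 2.0, 4.0, 4.0])

# stoichiometry matrix: columns = reactions (tetramerization, K2, K3, K4)
_STOICH = np.array(
    [
        #  L    K2   K3   K4
        [0.0, -1.0, -1.0, -1.0],  # O
        [-2.0, -1.0, 0.0, 0.0],  # R2
        [1.0, 0.0, -1.0, 0.0],  # R4
        [0.0, 1.0, 0.0, 0.0],  # R2O
        [0.0, 0.0, 1.0, -1.0],  # R4O
        [0.0, 0.0, 0.0, 1.0],  # R4O2
    ]
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReactionNetwork:
    """Scheme of RecO binding to RecR in a dimer-tetramer equilibrium.

    ``species`` maps the six names in :data:`SPECIES_ORDER` to
    :class:`~assemblink.hydro.Species`.  Equilibrium constants in M^-1;
    ``k_off`` reverse rates in s^-1 per reaction (tetramerization, K2, K3,
    K4 order).  With ``apply_statistical_factors`` the mass-action constants
    for the two tetramer sites get the 2x / 0.5x site-statistics conversion.
    """

    species: dict[str, Species]
    L_obs: float = 2.16e5
    K2: float = 10.0
    K3: float = 5e5
    K4: float = 4e8
    k_off: tuple[float, float, float, float] = (0.01, 0.01, 0.01, 0.01)
    apply_statistical_factors: bool = False

    def __post_init__(self) -> None:
        for name in SPECIES_ORDER:
            if name not in self.species:
                raise InvalidInputError(f"ReactionNetwork: missing species {name!r}")
        for K in (self.L_obs, self.K2, self.K3, self.K4):
            if K < 0:
                raise InvalidInputError("ReactionNetwork: equilibrium constants must be >= 0")
        if any(k < 0 for k in self.k_off):
            raise InvalidInputError("ReactionNetwork: reverse rates must be >= 0")

    @property
    def mass_action_constants(self) -> np.ndarray:
        """(L, K2, K3, K4) as used in mass action, after optional statistics."""
        K = np.array([self.L_obs, self.K2, self.K3, self.K4])
        if self.apply_statistical_factors:
            K[2] *= 2.0
            K[3] *= 0.5
        return K

    def rate_constants(self) -> tuple[np.ndarray, np.ndarray]:
        """(k_forward, k_reverse) arrays per reaction, k_f = K * k_off."""
        kb = np.asarray(self.k_off, dtype=float)
        return self.mass_action_constants * kb, kb


@dataclass(frozen=True)
class CellGeometry:
    """Sector cell geometry and rotor speed."""

    meniscus: float = 6.14  # cm
    bottom: float = 7.2  # cm
    rotor_speed: float = 42000.0  # rpm
    pathlength: float = 1.2  # cm
    n_radial: int = 400

    def __post_init__(self) -> None:
        if not self.meniscus < self.bottom:
            raise InvalidInputError("CellGeometry: meniscus must be < bottom")
        if self.n_radial < 100:
            raise InvalidInputError("CellGeometry: at least 100 radial points required")

    @property
    def omega(self) -> float:
        return self.rotor_speed * 2.0 * np.pi / 60.0

    def cell_centers(self) -> np.ndarray:
        edges = np.linspace(self.meniscus, self.bottom, self.n_radial + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class SVScanSet:
    """A set of simulated velocity scans (absorbance over radius per time)."""

    radii: np.ndarray  # cm, cell centers
    times: np.ndarray  # s
    absorbance: np.ndarray  # (ntimes, nradii) AU
    geometry: CellGeometry
    wavelength: float = 230.0
    noise_sd: float = 0.0
    concentrations: Optional[np.ndarray] = None  # (ntimes, nspecies, nradii), M

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("SVScanSet: times must be increasing")
        if self.absorbance.shape != (self.times.size, self.radii.size):
            raise InvalidInputError("SVScanSet: absorbance shape mismatch")


@dataclass
class CsDistribution:
    """Differential sedimentation-coefficient distribution c(s), AU per Svedberg."""

    s_grid: np.ndarray  # Svedberg
    c: np.ndarray  # AU/S, >= 0
    regularization: float
    frictional_ratio: float

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c < -1e-12):
            raise InvalidInputError("CsDistribution: amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# Default species table and network builders
# ---------------------------------------------------------------------------

#: per-species defaults: (mass kDa, vbar ml/g, s in buffer S, eps230 M^-1 cm^-1)
_SPECIES_TABLE = {
    "O": (27.4, 0.734, 0.8, 1.55e5),
    "R2": (43.9, 0.711, 1.2, 2 * 5.3e4),
    "R4": (87.8, 0.711, 1.7, 4 * 5.3e4),
    "R2O": (71.3, 0.720, 1.4, 1.55e5 + 2 * 5.3e4),
    "R4O": (115.2, 0.716, 1.9, 1.55e5 + 4 * 5.3e4),
    "R4O2": (142.6, 0.720, 2.5, 2 * 1.55e5 + 4 * 5.3e4),
}


def default_network(variant: str = "no_p15", **overrides) -> ReactionNetwork:
    """Reaction network with the standard species table.

    ``variant`` selects the binding constants: ``"no_p15"`` (K3=5e5,
    K4=4e8 M^-1, positively cooperative) or ``"plus_p15"`` (K3=2.5e8,
    K4=1e7 M^-1, negatively cooperative).  Keyword overrides are applied on
    top.
    """
    species = {
        name: Species(name=name, molar_mass=m, vbar=v, s_buffer=s, extinction=e)
        for name, (m, v, s, e) in _SPECIES_TABLE.items()
    }
    if variant == "no_p15":
        kw = dict(K3=5e5, K4=4e8)
    elif variant == "plus_p15":
        kw = dict(K3=2.5e8, K4=1e7)
    else:
        raise InvalidInputError(f"default_network: unknown variant {variant!r}")
    kw.update(overrides)
    return ReactionNetwork(species=species, **kw)


# ---------------------------------------------------------------------------
# Equilibrium speciation and kinetics
# ---------------------------------------------------------------------------


def equilibrium_composition(
    totals: tuple[float, float], network: ReactionNetwork, xtol: float = 1e-14
) -> dict[str, float]:
    """Equilibrium concentrations of all six species.

    ``totals`` = (total RecO in monomers, total RecR in monomers), both M.
    Solves the coupled mass-action/mass-balance system by one-dimensional
    root finding on free O nested with the (always solvable) quadratic for
    free R2; the system is monotone so the positive root is unique.
    """
    O_tot, R_tot = totals
    if O_tot < 0 or R_tot < 0:
        raise InvalidInputError("equilibrium_composition: totals must be >= 0")
    L, K2, K3, K4 = network.mass_action_constants

    def free_R2(x: float) -> float:
        a = 4.0 * L * (1.0 + K3 * x + K3 * K4 * x * x)
        b = 2.0 * (1.0 + K2 * x)
        if R_tot == 0.0:
            return 0.0
        if a == 0.0:
            return R_tot / b
        return 2.0 * R_tot / (b + np.sqrt(b * b + 4.0 * a * R_tot))

    def o_balance(x: float) -> float:
        y = free_R2(x)
        y2 = y * y
        return x * (1.0 + K2 * y + K3 * L * y2 + 2.0 * K3 * K4 * L * x * y2) - O_tot

    if O_tot == 0.0:
        x = 0.0
    else:
        x = brentq(o_balance, 0.0, O_tot, xtol=xtol * max(O_tot, 1e-30), rtol=8.9e-16)
    y = free_R2(x)
    conc = {
        "O": x,
        "R2": y,
        "R4": L * y * y,
        "R2O": K2 * x * y,
        "R4O": K3 * x * L * y * y,
        "R4O2": K3 * K4 * L * x * x * y * y,
    }
    return conc


def reaction_fluxes(concentrations: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Net d(concentration)/dt from reactions alone.

    ``concentrations`` has shape (6, ...) in :data:`SPECIES_ORDER` order.
    Conserves total O and total R monomer exactly; vanishes at the
    equilibrium composition.
    """
    c = np.asarray(concentrations, dtype=float)
    if c.shape[0] != 6:
        raise InvalidInputError("reaction_fluxes: expected 6 species rows")
    kf, kb = network.rate_constants()
    r = _reaction_rates(c, kf, kb)
    return np.einsum("ij,j...->i...", _STOICH, r)


def _reaction_rates(c: np.ndarray, kf: np.ndarray, kb: np.ndarray) -> np.ndarray:
    O, R2, R4, R2O, R4O, R4O2 = c
    return np.stack(
        [
            kf[0] * R2 * R2 - kb[0] * R4,
            kf[1] * R2 * O - kb[1] * R2O,
            kf[2] * R4 * O - kb[2] * R4O,
            kf[3] * R4O * O - kb[3] * R4O2,
        ]
    )


def _reaction_jacobian(c: np.ndarray, kf: np.ndarray, kb: np.ndarray) -> np.ndarray:
    """d(rates)/d(conc), shape (4, 6, ncells)."""
    O, R2, R4, R2O, R4O, R4O2 = c
    n = c.shape[1]
    J = np.zeros((4, 6, n))
    J[0, 1] = 2.0 * kf[0] * R2
    J[0, 2] = -kb[0]
    J[1, 0] = kf[1] * R2
    J[1, 1] = kf[1] * O
    J[1, 3] = -kb[1]
    J[2, 0] = kf[2] * R4
    J[2, 2] = kf[2] * O
    J[2, 4] = -kb[2]
    J[3, 0] = kf[3] * R4O
    J[3, 4] = kf[3] * O
    J[3, 5] = -kb[3]
    return J


def _reaction_step_implicit(
    c: np.ndarray, dt: float, kf: np.ndarray, kb: np.ndarray, tol: float = 1e-12, max_newton: int = 25
) -> np.ndarray:
    """Backward-Euler reaction substep, Newton iteration batched over cells.

    Preserves both linear conservation laws exactly at the converged solution.
    Returns None-equivalent failure by raising if Newton stalls.
    """
    ncells = c.shape[1]
    cn = c.copy()
    scale = max(float(np.max(np.abs(c))), 1e-30)
    eye = np.eye(6)
    for _ in range(max_newton):
        r = _reaction_rates(cn, kf, kb)
        F = cn - c - dt * np.einsum("ij,jk->ik", _STOICH, r)
        if float(np.max(np.abs(F))) < tol * scale:
            break
        Jr = _reaction_jacobian(cn, kf, kb)  # (4, 6, ncells)
        # J_F = I - dt * S @ Jr  per cell
        SJ = np.einsum("ij,jkl->ikl", _STOICH, Jr)  # (6, 6, ncells)
        A = eye[:, :, None] - dt * SJ
        delta = np.linalg.solve(A.transpose(2, 0, 1), F.T[..., None])[..., 0].T
        cn = cn - delta
    else:
        raise RuntimeError("reaction substep: Newton iteration did not converge")
    return cn


# ---------------------------------------------------------------------------
# Lamm solver
# ---------------------------------------------------------------------------


def _transport_matrix(
    geometry: CellGeometry, s: float, D: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal transport operator dc/dt = A c on the FV grid (cgs units).

    Upwind advection (v = s w^2 r > 0 everywhere), central diffusion,
    zero-flux boundaries.  Returns the three diagonals (lower, main, upper).
    """
    nr = geometry.n_radial
    r = geometry.cell_centers()
    dr = (geometry.bottom - geometry.meniscus) / nr
    rf = np.linspace(geometry.meniscus, geometry.bottom, nr + 1)  # interfaces
    w2 = geometry.omega**2
    v = s * SVEDBERG * w2 * rf  # cm/s at interfaces

    lower = np.zeros(nr)
    main = np.zeros(nr)
    upper = np.zeros(nr)
    # interior interface i+1/2 between cells i, i+1 (i = 0..nr-2):
    # flux = v*c_i (upwind) - D*(c_{i+1}-c_i)/dr, scaled by rf
    for_i = np.arange(nr - 1)
    coef = rf[1:-1] / dr
    adv = v[1:-1]
    # contribution to cell i (outflow) and cell i+1 (inflow)
    # dc_i/dt -= (rf*J)/ (r_i dr);  dc_{i+1}/dt += (rf*J)/(r_{i+1} dr)
    out_i = coef / r[for_i]
    in_i = coef / r[for_i + 1]
    main[for_i] += -out_i * (adv + D / dr)
    upper[for_i] += out_i * (D / dr)
    lower[for_i] += in_i * (adv + D / dr)
    main[for_i + 1] += -in_i * (D / dr)
    return lower, main, upper


def _cn_banded(lower, main, upper, dt, theta=0.5):
    """Banded (I - theta dt A) and explicit-part diagonals for CN stepping."""
    nr = main.size
    ab = np.zeros((3, nr))
    ab[0, 1:] = -theta * dt * upper[:-1]
    ab[1, :] = 1.0 - theta * dt * main
    ab[2, :-1] = -theta * dt * lower[:-1]
    return ab


def _cn_rhs(lower, main, upper, c, dt, theta=0.5):
    expl = (1.0 - theta) * dt
    rhs = c * (1.0 + expl * main)
    rhs[:-1] += expl * upper[:-1] * c[1:]
    rhs[1:] += expl * lower[:-1] * c[:-1]
    return rhs


def simulate_lamm(
    network: ReactionNetwork,
    totals: tuple[float, float],
    geometry: CellGeometry,
    times: Sequence[float],
    buffer: BufferState,
    dt_max: float = 5.0,
    with_reactions: bool = True,
    initial: Optional[np.ndarray] = None,
    store_concentrations: bool = False,
) -> SVScanSet:
    """Simulate sedimentation-velocity scans of the reacting system.

    Starts from a uniform column at the equilibrium composition of ``totals``
    (total O, total R in monomers; M), unless ``initial`` (shape (6, nr))
    is given.  Species diffusion coefficients come from the Svedberg relation
    applied to each species' buffer s.  Returns absorbance scans
    A = pathlength * sum_i eps_i c_i at the requested ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times < 0):
        raise InvalidInputError("simulate_lamm: times must be nonnegative")
    if np.any(times > 7200.0):
        raise InvalidInputError("simulate_lamm: times must lie within 0-2 h")
    nr = geometry.n_radial
    r = geometry.cell_centers()

    # per-species transport operators
    diags = []
    eps = np.empty(6)
    for j, name in enumerate(SPECIES_ORDER):
        sp = network.species[name]
        s = sp.s_buffer
        D_cm2 = diffusion_from_s(s, sp.molar_mass, sp.vbar, buffer) if s > 0 else 0.0
        diags.append(_transport_matrix(geometry, s, D_cm2))
        eps[j] = sp.extinction

    if initial is None:
        comp = equilibrium_composition(totals, network)
        c = np.tile(np.array([comp[n] for n in SPECIES_ORDER])[:, None], (1, nr))
    else:
        c = np.asarray(initial, dtype=float).copy()
        if c.shape != (6, nr):
            raise InvalidInputError("simulate_lamm: initial must have shape (6, n_radial)")

    kf, kb = network.rate_constants()
    do_react = with_reactions and (np.any(kf > 0) or np.any(kb > 0))

    def step(c, dt):
        if do_react:
            c = _reaction_step_implicit(c, dt / 2.0, kf, kb)
        for j in range(6):
            lower, main, upper = diags[j]
            ab = _cn_banded(lower, main, upper, dt)
            rhs = _cn_rhs(lower, main, upper, c[j], dt)
            c[j] = solve_banded((1, 1), ab, rhs)
        if do_react:
            c = _reaction_step_implicit(c, dt / 2.0, kf, kb)
        return c

    dt_floor = 1e-3

    def advance(c, t0, t1):
        span = t1 - t0
        if span <= 0:
            return c
        dt = dt_max
        # automatic refinement: halve the step when the stiff reaction
        # substep fails to converge; hard error at the floor
        while True:
            try:
                nsteps = max(int(np.ceil(span / dt)), 1)
                h = span / nsteps
                cc = c.copy()
                for _ in range(nsteps):
                    cc = step(cc, h)
                return cc
            except RuntimeError:
                dt /= 2.0
                if dt < dt_floor:
                    raise RuntimeError(
                        "simulate_lamm: step-size floor reached without convergence"
                    ) from None

    scans = np.empty((times.size, nr))
    stored = np.empty((times.size, 6, nr)) if store_concentrations else None
    t_now = 0.0
    for k, t in enumerate(times):
        c = advance(c, t_now, t)
        t_now = t
        scans[k] = geometry.pathlength * (eps @ c)
        if store_concentrations:
            stored[k] = c

    return SVScanSet(
        radii=r,
        times=times,
        absorbance=scans,
        geometry=geometry,
        noise_sd=0.0,
        concentrations=stored,
    )


def sector_integral(field: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Sector integral int f r dr on the FV grid (cell sum; exact for FV fields).

    ``field`` may have any leading shape with radius last.  This is the
    discretely conserved measure of the solver — prefer it over trapezoidal
    quadrature, which under-weights the boundary cells where material
    accumulates.
    """
    dr = radii[1] - radii[0]
    return np.sum(field * radii, axis=-1) * dr


def conserved_totals(scans: SVScanSet) -> tuple[np.ndarray, np.ndarray]:
    """Sector-integrated total O and total R monomer per scan time.

    Requires the scan set to carry species concentrations
    (``store_concentrations=True`` in :func:`simulate_lamm`).
    """
    if scans.concentrations is None:
        raise InvalidInputError("conserved_totals: scan set carries no concentrations")
    o = sector_integral(np.einsum("j,tjr->tr", _O_CONTENT, scans.concentrations), scans.radii)
    r = sector_integral(np.einsum("j,tjr->tr", _R_CONTENT, scans.concentrations), scans.radii)
    return o, r


def add_noise(scans: SVScanSet, sd: float, seed: int) -> SVScanSet:
    """Add i.i.d. Gaussian noise of standard deviation ``sd`` AU (seeded)."""
    if sd < 0:
        raise InvalidInputError("add_noise: sd must be >= 0")
    if sd == 0.0:
        return scans
    rng = np.random.default_rng(seed)
    noisy = scans.absorbance + rng.normal(0.0, sd, size=scans.absorbance.shape)
    return replace(scans, absorbance=noisy, noise_sd=float(np.hypot(scans.noise_sd, sd)))


# ---------------------------------------------------------------------------
# c(s)-style distribution and weight-average s
# ---------------------------------------------------------------------------


def diffusion_for_s_grid(
    s: np.ndarray, frictional_ratio: float, vbar: float, buffer: BufferState
) -> np.ndarray:
    """D(s) (cm^2/s) under the standard frictional-ratio scaling.

    f = (6 pi eta f/f0)^(3/2) * (3 vbar s / (4 pi (1 - vbar rho)))^(1/2),
    D = kB T / f, all SI internally.
    """
    s_si = np.asarray(s, dtype=float) * SVEDBERG
    eta = buffer.viscosity * 1e-3  # Pa s
    rho = buffer.density * 1e3  # kg/m^3
    vb = vbar * 1e-3  # m^3/kg
    buoy = 1.0 - vb * rho
    if buoy <= 0:
        raise InvalidInputError("diffusion_for_s_grid: neutral/negative buoyancy")
    f = (6.0 * np.pi * eta * frictional_ratio) ** 1.5 * np.sqrt(
        3.0 * vb * s_si / (4.0 * np.pi * buoy)
    )
    return _KB * buffer.temperature / f * 1e4  # cm^2/s


def frictional_ratio_equivalent(sp: Species, buffer: BufferState) -> float:
    """f/f0 implied by a species' (s, M, vbar) with D from the Svedberg relation.

    Useful for choosing a c(s) grid frictional ratio consistent with the
    species being simulated.
    """
    D = diffusion_from_s(sp.s_buffer, sp.molar_mass, sp.vbar, buffer) * 1e-4  # m^2/s
    f = _KB * buffer.temperature / D
    eta = buffer.viscosity * 1e-3
    rho = buffer.density * 1e3
    vb = sp.vbar * 1e-3
    buoy = 1.0 - vb * rho
    q = np.sqrt(3.0 * vb * sp.s_buffer * SVEDBERG / (4.0 * np.pi * buoy))
    return float((f / q) ** (2.0 / 3.0) / (6.0 * np.pi * eta))


def _single_species_basis(
    s: float, D_cm2: float, geometry: CellGeometry, times: np.ndarray, dt_max: float = 30.0
) -> np.ndarray:
    """Unit-plateau non-reacting Lamm solution, flattened over (times, radii)."""
    nr = geometry.n_radial
    lower, main, upper = _transport_matrix_cm(geometry, s, D_cm2)
    c = np.ones(nr)
    out = np.empty((times.size, nr))
    t_now = 0.0
    for k, t in enumerate(times):
        span = t - t_now
        if span > 0:
            nsteps = max(int(np.ceil(span / dt_max)), 1)
            dt = span / nsteps
            ab = _cn_banded(lower, main, upper, dt)
            for _ in range(nsteps):
                rhs = _cn_rhs(lower, main, upper, c, dt)
                c = solve_banded((1, 1), ab, rhs)
        t_now = t
        out[k] = c
    return out.ravel()


def _transport_matrix_cm(geometry, s, D_cm2):
    return _transport_matrix(geometry, s, D_cm2)


def fit_cs(
    scans: SVScanSet,
    s_grid: np.ndarray,
    frictional_ratio: float = 1.5,
    regularization: float = 0.1,
    vbar: float = 0.72,
    buffer: Optional[BufferState] = None,
    dt_max: float = 30.0,
    optimize_fr: bool = False,
    fr_grid: Sequence[float] = (1.4, 1.5, 1.6, 1.7, 1.8),
    exclude_bottom_cm: float = 0.1,
    exclude_meniscus_cm: float = 0.01,
) -> CsDistribution:
    """Nonnegative regularized fit of scans to single-species Lamm solutions.

    Solves min ||B w - y||^2 + lambda^2 ||L w||^2 with w >= 0 where columns of
    B are unit-signal Lamm solutions on the s grid and L is the second
    difference.  The penalty weight ``regularization`` is an absolute lambda
    in AU; the default 0.1 perturbs the fit at roughly the level of typical
    scan noise (5e-3 AU over thousands of points) so peak positions are not
    biased.  c(s) = w / ds so that the integral of c(s) ds equals the fitted
    total loading signal.

    With ``optimize_fr`` the scalar frictional ratio is chosen from
    ``fr_grid`` by smallest data residual — a coarse stand-in for the usual
    c(s) practice of optimizing f/f0, without its full nonlinear refinement.

    Following standard practice the fit range excludes the optical artifacts
    of the cell ends: ``exclude_bottom_cm`` of back-diffusion/accumulation at
    the base and ``exclude_meniscus_cm`` at the meniscus.
    """
    if scans.times.size < 10:
        raise InvalidInputError("fit_cs: need >= 10 scans spanning boundary movement")
    s_grid = np.asarray(s_grid, dtype=float)
    if buffer is None:
        buffer = BufferState(density=1.0, viscosity=1.0)
    geom = scans.geometry
    keep = (scans.radii >= geom.meniscus + exclude_meniscus_cm) & (
        scans.radii <= geom.bottom - exclude_bottom_cm
    )
    y = scans.absorbance[:, keep].ravel()
    if not np.any(np.abs(y) > 0):
        return CsDistribution(
            s_grid=s_grid, c=np.zeros(s_grid.size), regularization=regularization,
            frictional_ratio=frictional_ratio,
        )
    ns = s_grid.size
    L = np.zeros((ns - 2, ns))
    for i in range(ns - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)

    def solve(fr: float) -> tuple[np.ndarray, float]:
        Dgrid = diffusion_for_s_grid(s_grid, fr, vbar, buffer)
        nt, nr = scans.times.size, scans.radii.size
        B = np.column_stack(
            [
                _single_species_basis(s, D, scans.geometry, scans.times, dt_max)
                .reshape(nt, nr)[:, keep]
                .ravel()
                for s, D in zip(s_grid, Dgrid)
            ]
        )
        A = np.vstack([B, regularization * L])
        rhs = np.concatenate([y, np.zeros(ns - 2)])
        w, _ = nnls(A, rhs)
        resid = float(np.linalg.norm(B @ w - y))
        return w, resid

    if optimize_fr:
        best_fr, (w, _) = min(
            ((fr, solve(fr)) for fr in fr_grid), key=lambda t: t[1][1]
        )
        frictional_ratio = best_fr
    else:
        w, _ = solve(frictional_ratio)
    ds = np.gradient(s_grid)
    return CsDistribution(
        s_grid=s_grid, c=w / ds, regularization=regularization, frictional_ratio=frictional_ratio
    )


def weight_average_s(
    dist: CsDistribution, s_range: Optional[tuple[float, float]] = None
) -> float:
    """Signal-weighted average s over a range: int s c(s) ds / int c(s) ds."""
    s, c = dist.s_grid, dist.c
    if s_range is not None:
        mask = (s >= s_range[0]) & (s <= s_range[1])
        s, c = s[mask], c[mask]
    if s.size == 0 or np.trapezoid(c, s) <= 0:
        raise InvalidInputError("weight_average_s: zero signal in range")
    return float(np.trapezoid(s * c, s) / np.trapezoid(c, s))


def transport_sw(
    scans: SVScanSet, plateau_window: tuple[float, float], min_plateau: float = 1e-3
) -> float:
    """Model-free weight-average s from the transport (second-moment) method.

    The sector integral Q(t) = int_m^rp A r dr obeys dQ/dt = -s w^2 rp^2 c_p(t)
    in the plateau, so s is the slope of Q against the cumulative plateau
    exposure X(t) = -w^2 rp^2 int c_p dt'.  The regression over all scans is
    exact under radial dilution (c_p measured per scan) and averages the noise
    down; the sector integral uses the FV cell-sum quadrature.
    """
    r = scans.radii
    lo, hi = plateau_window
    win = (r >= lo) & (r <= hi)
    if not np.any(win):
        raise InvalidInputError("transport_sw: empty plateau window")
    rp = 0.5 * (lo + hi)
    upto = r <= rp
    w2 = scans.geometry.omega**2

    plateaus = scans.absorbance[:, win].mean(axis=1)
    slopes = [abs(np.polyfit(r[win], a[win], 1)[0]) for a in scans.absorbance]
    if np.any(plateaus < min_plateau):
        raise InvalidInputError("transport_sw: no identifiable plateau (signal too low)")
    span = hi - lo
    if np.any(np.asarray(slopes) * span > 0.2 * plateaus):
        raise InvalidInputError("transport_sw: window is not a plateau")

    dr = r[1] - r[0]
    Q = (scans.absorbance[:, upto] * r[upto]).sum(axis=1) * dr
    t = scans.times
    # cumulative plateau exposure (trapezoid in time)
    mid_cp = 0.5 * (plateaus[1:] + plateaus[:-1])
    X = np.concatenate([[0.0], np.cumsum(mid_cp * np.diff(t))]) * w2 * rp**2
    X = -X
    sw = float(np.polyfit(X, Q, 1)[0]) / SVEDBERG
    return sw
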