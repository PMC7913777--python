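"""Sedimentation-equilibrium forward models and global fitting.

At sedimentation equilibrium the radial absorbance profile of each ideal
species is exponential in r^2:

    A(r) = sum_i A0_i exp[ M_i (1 - vbar_i rho) omega^2 / (2RT) (r^2 - r0^2) ] + b

For a self-associating dimer-tetramer system with equilibrium constant
L_obs = [R4]/[R2]^2, the tetramer profile is slaved to the dimer profile
(its exponent is exactly twice the dimer exponent):

    c_total(r) = c2_0 e^phi + L_obs c2_0^2 e^(2 phi)

Global fitting shares the thermodynamic parameters (molar masses, L_obs)
across rotor speeds and loading concentrations while floating per-scan
amplitudes and baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .hydro import GAS_CONSTANT, BufferState, InvalidInputError

__all__ = [
    "SEScan",
    "SESpeciesSpec",
    "SEModelSpec",
    "SEFitResult",
    "se_exponent",
    "predict_profile_species",
    "predict_profile_dimer_tetramer",
    "fit_global",
    "species_fractions",
    "column_total_signal",
]


def _omega(rpm: float) -> float:
    return rpm * 2.0 * np.pi / 60.0


def se_exponent(
    molar_mass: float, vbar: float, buffer: BufferState, rpm: float, radii: np.ndarray, r0: float
) -> np.ndarray:
    """Reduced buoyant exponent M(1-vbar rho) omega^2/(2RT) (r^2-r0^2), radii in cm."""
    w2 = _omega(rpm) ** 2
    # (r^2 - r0^2) in cm^2 -> m^2
    dr2 = (np.asarray(radii, dtype=float) ** 2 - r0**2) * 1e-4
    return (
        molar_mass
        * (1.0 - vbar * buffer.density)
        * w2
        / (2.0 * GAS_CONSTANT * buffer.temperature)
        * dr2
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SEScan:
    """One equilibrium radial absorbance scan."""

    radii: np.ndarray  # cm, strictly increasing
    absorbance: np.ndarray  # AU
    rotor_speed: float  # rpm
    wavelength: float = 230.0  # nm
    channel: str = "A"
    meniscus: float = 0.0  # cm
    bottom: float = 0.0  # cm

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radii.shape != self.absorbance.shape:
            raise InvalidInputError("SEScan: radii and absorbance must have the same length")
        if self.radii.size < 20:
            raise InvalidInputError("SEScan: at least 20 radial points required")
        if np.any(np.diff(self.radii) <= 0):
            raise InvalidInputError("SEScan: radii must be strictly increasing")
        if not (self.meniscus < self.radii[0] <= self.radii[-1] <= self.bottom):
            raise InvalidInputError("SEScan: require meniscus < min(radii) <= max(radii) <= bottom")


@dataclass
class SESpeciesSpec:
    """One species entry in a species-mode model."""

    molar_mass: float  # kDa
    vbar: float  # ml/g
    fixed_mass: bool = True
    amplitude: float = 0.1  # A(r0) initial guess, AU


@dataclass
class SEModelSpec:
    """Model specification for SE fitting.

    ``mode`` is ``"species"`` (sum of independent exponentials, Eq. of the
    multi-species ideal model) or ``"dimer-tetramer"`` (self-association with
    the tetramer term slaved to the dimer).  ``r0`` of ``None`` means "use
    each scan's meniscus" so amplitudes are directly interpretable.
    """

    mode: str = "species"
    species: list[SESpeciesSpec] = field(default_factory=list)
    r0: Optional[float] = None
    fit_baselines: bool = True
    # dimer-tetramer mode
    dimer_mass: float = 43.9  # kDa
    dimer_vbar: float = 0.711  # ml/g
    L_obs: float = 1e5  # M^-1, initial guess / fixed value
    fit_L: bool = True
    signal_coeff: float = 1.06e5 * 1.2  # AU per M of dimer (eps * pathlength)
    # mass-conservation penalty (species mode): weight on equality of sector
    # integrals across rotor speeds within one channel; 0 disables
    conservation_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("species", "dimer-tetramer"):
            raise InvalidInputError(f"SEModelSpec: unknown mode {self.mode!r}")
        if self.L_obs < 0:
            raise InvalidInputError("SEModelSpec: L_obs must be >= 0")


@dataclass
class SEFitResult:
    """Fitted parameters with asymptotic standard errors and diagnostics."""

    parameters: dict[str, float]
    stderr: dict[str, float]
    rmsd_per_scan: list[float]
    residuals: list[np.ndarray]
    converged: bool
    objective: float
    n_multistarts: int = 1
    warnings: list[str] = field(default_factory=list)

    @property
    def rmsd(self) -> float:
        n = sum(r.size for r in self.residuals)
        return float(np.sqrt(sum(float(r @ r) for r in self.residuals) / n))


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def predict_profile_species(
    spec: SEModelSpec,
    radii: np.ndarray,
    rpm: float,
    buffer: BufferState,
    r0: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Multi-species ideal SE profile: sum of exponentials plus baseline."""
    if spec.mode != "species":
        raise InvalidInputError("predict_profile_species: spec must be in 'species' mode")
    radii = np.asarray(radii, dtype=float)
    out = np.full_like(radii, baseline, dtype=float)
    for sp in spec.species:
        out += sp.amplitude * np.exp(se_exponent(sp.molar_mass, sp.vbar, buffer, rpm, radii, r0))
    return out


def predict_profile_dimer_tetramer(
    spec: SEModelSpec,
    radii: np.ndarray,
    rpm: float,
    buffer: BufferState,
    r0: float,
    c_di_r0: float,
    baseline: float = 0.0,
    as_absorbance: bool = True,
) -> np.ndarray:
    """Dimer-tetramer SE profile.

    Concentrations: c2(r) = c2_0 e^phi, c4(r) = L_obs c2(r)^2; the tetramer
    exponent is exactly 2 phi.  With ``as_absorbance`` the dimer signal
    coefficient ``spec.signal_coeff`` applies, and the tetramer carries twice
    the dimer's chromophores.  L_obs = 0 reduces to the single-species dimer
    profile.
    """
    if spec.mode != "dimer-tetramer":
        raise InvalidInputError("predict_profile_dimer_tetramer: spec must be in 'dimer-tetramer' mode")
    if spec.L_obs < 0:
        raise InvalidInputError("predict_profile_dimer_tetramer: negative L_obs")
    phi = se_exponent(spec.dimer_mass, spec.dimer_vbar, buffer, rpm, np.asarray(radii, float), r0)
    c2 = c_di_r0 * np.exp(phi)
    c4 = spec.L_obs * c_di_r0**2 * np.exp(2.0 * phi)
    if as_absorbance:
        return spec.signal_coeff * (c2 + 2.0 * c4) + baseline
    return c2 + c4 + baseline


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


def _fit_errors(res, n_data: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    ndof = max(n_data - res.x.size, 1)
    s2 = 2.0 * res.cost / ndof
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


def fit_global(
    scans: Sequence[SEScan],
    spec: SEModelSpec,
    buffer: BufferState,
    n_multistarts: int = 8,
    seed: int = 0,
) -> SEFitResult:
    """Global NLLS fit of one model across scans (speeds and loadings).

    Thermodynamic parameters (floated molar masses or log10 L_obs) are shared
    globally; per-scan amplitudes (log scale, enforcing positivity) and
    optional per-scan constant baselines are local.  Multistarts perturb the
    shared association constant log-uniformly over +-2 decades (seeded);
    the lowest objective wins.
    """
    if len(scans) == 0:
        raise InvalidInputError("fit_global: need at least one scan")
    rng = np.random.default_rng(seed)
    n_data = sum(s.radii.size for s in scans)

    if spec.mode == "dimer-tetramer":
        return _fit_dimer_tetramer(scans, spec, buffer, rng, n_multistarts, n_data)
    return _fit_species(scans, spec, buffer, rng, n_multistarts, n_data)


def _scan_r0(spec: SEModelSpec, scan: SEScan) -> float:
    return spec.r0 if spec.r0 is not None else scan.meniscus


def _fit_dimer_tetramer(scans, spec, buffer, rng, n_multistarts, n_data) -> SEFitResult:
    ns = len(scans)
    phis = [
        se_exponent(spec.dimer_mass, spec.dimer_vbar, buffer, s.rotor_speed, s.radii, _scan_r0(spec, s))
        for s in scans
    ]

    # initial amplitude guesses from the shallowest part of each scan
    c0_guess = []
    for s in scans:
        a0 = max(float(np.min(s.absorbance)), 1e-4)
        c0_guess.append(a0 / spec.signal_coeff)

    def unpack(x):
        k = 0
        if spec.fit_L:
            L = 10.0 ** x[k]
            k += 1
        else:
            L = spec.L_obs
        c0 = 10.0 ** x[k : k + ns]
        k += ns
        b = x[k : k + ns] if spec.fit_baselines else np.zeros(ns)
        return L, c0, b

    def residuals(x):
        L, c0, b = unpack(x)
        out = []
        for i, s in enumerate(scans):
            c2 = c0[i] * np.exp(phis[i])
            model = spec.signal_coeff * (c2 + 2.0 * L * c2**2) + b[i]
            out.append(model - s.absorbance)
        return np.concatenate(out)

    def solve(logL0):
        x0, lb, ub = [], [], []
        if spec.fit_L:
            x0.append(np.clip(logL0, -10.0, 12.0))
            lb.append(-12.0)
            ub.append(14.0)
        x0.extend(np.log10(c0_guess))
        lb.extend([-12.0] * ns)
        ub.extend([0.0] * ns)
        if spec.fit_baselines:
            x0.extend([0.0] * ns)
            lb.extend([-1.0] * ns)
            ub.extend([1.0] * ns)
        return least_squares(
            residuals, np.asarray(x0), bounds=(lb, ub), method="trf", x_scale="jac"
        )

    base_logL = np.log10(max(spec.L_obs, 1e-30)) if spec.fit_L else 0.0
    starts = [base_logL]
    if spec.fit_L and n_multistarts > 1:
        starts += list(base_logL + rng.uniform(-2.0, 2.0, size=n_multistarts - 1))
    best = min((solve(s0) for s0 in starts), key=lambda r: r.cost)

    L, c0, b = unpack(best.x)
    err = _fit_errors(best, n_data)
    params: dict[str, float] = {}
    stderr: dict[str, float] = {}
    k = 0
    if spec.fit_L:
        params["L_obs"] = L
        stderr["L_obs"] = L * np.log(10.0) * err[k]
        k += 1
    for i in range(ns):
        params[f"c_di_r0[{i}]"] = c0[i]
        stderr[f"c_di_r0[{i}]"] = c0[i] * np.log(10.0) * err[k]
        k += 1
    if spec.fit_baselines:
        for i in range(ns):
            params[f"baseline[{i}]"] = b[i]
            stderr[f"baseline[{i}]"] = err[k]
            k += 1

    return _package(best, scans, params, stderr, len(starts))


def _fit_species(scans, spec, buffer, rng, n_multistarts, n_data) -> SEFitResult:
    ns = len(scans)
    nsp = len(spec.species)
    if nsp == 0:
        raise InvalidInputError("fit_global: species mode requires at least one species")
    float_idx = [j for j, sp in enumerate(spec.species) if not sp.fixed_mass]

    def unpack(x):
        k = 0
        masses = [sp.molar_mass for sp in spec.species]
        for j in float_idx:
            masses[j] = 10.0 ** x[k]
            k += 1
        amps = 10.0 ** x[k : k + ns * nsp].reshape(ns, nsp)
        k += ns * nsp
        b = x[k : k + ns] if spec.fit_baselines else np.zeros(ns)
        return masses, amps, b

    def model_scan(i, scan, masses, amps, b):
        r0 = _scan_r0(spec, scan)
        out = np.full(scan.radii.size, b[i])
        for j, sp in enumerate(spec.species):
            phi = se_exponent(masses[j], sp.vbar, buffer, scan.rotor_speed, scan.radii, r0)
            out = out + amps[i, j] * np.exp(phi)
        return out

    channels: dict[str, list[int]] = {}
    for i, s in enumerate(scans):
        channels.setdefault(s.channel, []).append(i)

    def residuals(x):
        masses, amps, b = unpack(x)
        out = []
        models = []
        for i, s in enumerate(scans):
            m = model_scan(i, s, masses, amps, b)
            models.append(m)
            out.append(m - s.absorbance)
        if spec.conservation_weight > 0:
            w = np.sqrt(spec.conservation_weight)
            for idxs in channels.values():
                if len(idxs) < 2:
                    continue
                ints = [
                    np.trapezoid((models[i] - b[i]) * scans[i].radii, scans[i].radii)
                    for i in idxs
                ]
                mean_int = np.mean(ints)
                out.append(w * (np.asarray(ints) - mean_int))
        return np.concatenate(out)

    amp_guess = np.empty((ns, nsp))
    for i, s in enumerate(scans):
        lo = max(float(np.min(s.absorbance)), 1e-4)
        for j, sp in enumerate(spec.species):
            amp_guess[i, j] = max(sp.amplitude, lo / nsp)

    def solve(perturb):
        x0, lb, ub = [], [], []
        for j in float_idx:
            x0.append(np.log10(spec.species[j].molar_mass) + perturb)
            lb.append(0.0)  # 1 kDa
            ub.append(4.0)  # 10 MDa
        x0.extend(np.log10(amp_guess).ravel())
        lb.extend([-10.0] * ns * nsp)
        ub.extend([2.0] * ns * nsp)
        if spec.fit_baselines:
            x0.extend([0.0] * ns)
            lb.extend([-1.0] * ns)
            ub.extend([1.0] * ns)
        return least_squares(
            residuals, np.asarray(x0), bounds=(lb, ub), method="trf", x_scale="jac"
        )

    perturbs = [0.0]
    if float_idx and n_multistarts > 1:
        perturbs += list(rng.uniform(-0.3, 0.3, size=n_multistarts - 1))
    best = min((solve(p) for p in perturbs), key=lambda r: r.cost)

    masses, amps, b = unpack(best.x)
    err = _fit_errors(best, n_data)
    params: dict[str, float] = {}
    stderr: dict[str, float] = {}
    k = 0
    for j in float_idx:
        params[f"M[{j}]"] = masses[j]
        stderr[f"M[{j}]"] = masses[j] * np.log(10.0) * err[k]
        k += 1
    for i in range(ns):
        for j in range(nsp):
            params[f"A0[{i},{j}]"] = amps[i, j]
            stderr[f"A0[{i},{j}]"] = amps[i, j] * np.log(10.0) * err[k]
            k += 1
    if spec.fit_baselines:
        for i in range(ns):
            params[f"baseline[{i}]"] = b[i]
            stderr[f"baseline[{i}]"] = err[k]
            k += 1

    return _package(best, scans, params, stderr, len(perturbs))


def _package(best, scans, params, stderr, nstarts) -> SEFitResult:
    resid = []
    k = 0
    r_all = best.fun
    for s in scans:
        resid.append(r_all[k : k + s.radii.size])
        k += s.radii.size
    rmsds = [float(np.sqrt(np.mean(r**2))) for r in resid]
    warns = []
    if not best.success:
        warns.append("optimizer did not report convergence")
    return SEFitResult(
        parameters=params,
        stderr=stderr,
        rmsd_per_scan=rmsds,
        residuals=resid,
        converged=bool(best.success),
        objective=float(best.cost),
        n_multistarts=nstarts,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Species fractions and conservation integral
# ---------------------------------------------------------------------------


def species_fractions(L_obs: float, R_tot: float) -> tuple[float, float]:
    """Mass fractions (f_dimer, f_tetramer) at total dimer-unit concentration R_tot.

    Solves 2 L [R2]^2 + [R2] = R_tot for the free dimer concentration and
    returns f2 = [R2]/R_tot and f4 = 2 L [R2]^2 / R_tot, which sum to one.
    """
    if L_obs < 0:
        raise InvalidInputError("species_fractions: L_obs must be >= 0")
    if R_tot <= 0:
        raise InvalidInputError("species_fractions: R_tot must be > 0")
    if L_obs == 0.0:
        return 1.0, 0.0
    # stable quadratic root: c2 = (-1 + sqrt(1 + 8 L R)) / (4 L)
    c2 = 2.0 * R_tot / (1.0 + np.sqrt(1.0 + 8.0 * L_obs * R_tot))
    f2 = c2 / R_tot
    return float(f2), float(1.0 - f2)


def column_total_signal(scan: SEScan, coverage_warn: float = 0.9) -> float:
    """Sector-weighted integral of the scan, int A(r) r dr over the column (AU cm^2).

    For a conserved system this integral is identical across rotor speeds
    (within noise).  Warns if the scan covers less than ``coverage_warn`` of
    the meniscus-to-bottom column.
    """
    span = scan.radii[-1] - scan.radii[0]
    column = scan.bottom - scan.meniscus
    if column > 0 and span < coverage_warn * column:
        warnings.warn(
            f"column_total_signal: scan covers {span/column:.0%} of the column", stacklevel=2
        )
    return float(np.trapezoid(scan.absorbance * scan.radii, scan.radii))
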