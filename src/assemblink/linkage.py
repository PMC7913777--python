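"""pH linkage of the dimer-tetramer equilibrium.

The observed tetramerization constant L_obs = [R4]/[R2]^2 depends on pH
through protonation of both assembly states (Wyman linkage):

    L_obs(pH) = L0 * P_tet / P_di^2

with binding polynomials P = (1 + k [H+])^sites for identical independent
protonation sites and P = 1 + (k [H+])^sites for fully cooperative sites.
The pointwise slope d(log10 L_obs)/d(pH) equals the net number of protons
taken up on forming a tetramer from two dimers, Delta n_H+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .hydro import InvalidInputError

__all__ = [
    "LinkageModel",
    "PhSeries",
    "binding_polynomial",
    "log_L_model",
    "fit_linkage",
    "proton_uptake_slope",
    "rank_site_models",
]


@dataclass(frozen=True)
class LinkageModel:
    """Linkage parameters: L0 (M^-1), protonation constants (M^-1), site counts."""

    L0: float  # tetramerization constant of the unprotonated species, M^-1
    k_tet: float  # tetramer-site protonation constant, M^-1
    k_di: float  # dimer-site protonation constant, M^-1
    m: int = 3  # tetramer protonation sites
    n: int = 2  # dimer protonation sites
    coop_tet: bool = True
    coop_di: bool = False

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.k_tet <= 0 or self.k_di <= 0:
            raise InvalidInputError("LinkageModel: L0, k_tet, k_di must be > 0")
        if self.m < 0 or self.n < 0:
            raise InvalidInputError("LinkageModel: site counts must be >= 0")


@dataclass
class PhSeries:
    """Measured (pH, L_obs) table; rows flagged as upper limits carry no residual."""

    pH: np.ndarray
    L_obs: np.ndarray  # M^-1
    sigma: Optional[np.ndarray] = None  # SE of L_obs, M^-1
    upper_limit: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.L_obs = np.asarray(self.L_obs, dtype=float)
        if self.upper_limit is None:
            self.upper_limit = np.zeros(self.pH.size, dtype=bool)
        else:
            self.upper_limit = np.asarray(self.upper_limit, dtype=bool)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.pH) <= 0):
            raise InvalidInputError("PhSeries: pH must be strictly increasing")
        if np.any(self.L_obs <= 0):
            raise InvalidInputError("PhSeries: L_obs must be > 0")


def binding_polynomial(k: float, pH: float, sites: int, cooperative: bool = False) -> float:
    """Protonation binding polynomial, >= 1; tends to 1 as pH -> infinity.

    Independent sites: (1 + k*10^-pH)^sites.  Fully cooperative sites:
    1 + (k*10^-pH)^sites.
    """
    if k <= 0:
        raise InvalidInputError("binding_polynomial: k must be > 0")
    if sites < 0:
        raise InvalidInputError("binding_polynomial: sites must be >= 0")
    kh = k * 10.0 ** (-pH)
    if cooperative:
        return float(1.0 + kh**sites) if sites > 0 else 1.0
    return float((1.0 + kh) ** sites)


def _log10_1p_exp10(x: np.ndarray) -> np.ndarray:
    """log10(1 + 10**x), overflow-safe elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 30.0, x, np.log10(1.0 + 10.0 ** np.minimum(x, 30.0)))
    return out


def _log10_poly(k: float, h: np.ndarray, sites: int, cooperative: bool) -> np.ndarray:
    """log10 of the binding polynomial, overflow-safe for large k*h."""
    h = np.asarray(h, dtype=float)
    if sites == 0:
        return np.zeros_like(h)
    lkh = np.log10(k) + np.log10(h)
    if cooperative:
        return _log10_1p_exp10(sites * lkh)
    return sites * _log10_1p_exp10(lkh)


def log_L_model(model: LinkageModel, pH) -> np.ndarray | float:
    """log10 L_obs(pH) = log10 L0 + log10 P_tet - 2 log10 P_di."""
    ph = np.asarray(pH, dtype=float)
    h = 10.0 ** (-ph)
    out = (
        np.log10(model.L0)
        + _log10_poly(model.k_tet, h, model.m, model.coop_tet)
        - 2.0 * _log10_poly(model.k_di, h, model.n, model.coop_di)
    )
    return float(out) if np.isscalar(pH) else out


def proton_uptake_slope(model: LinkageModel, pH, interval: Optional[tuple[float, float]] = None) -> float:
    """Net proton uptake Delta n_H+ = d(log10 L_obs)/d(pH).

    Pointwise (analytic derivative) at ``pH``, or, if ``interval=(a, b)`` is
    given, the mean slope (log10 L(b) - log10 L(a)) / (b - a).
    """
    if interval is not None:
        a, b = interval
        return float((log_L_model(model, b) - log_L_model(model, a)) / (b - a))
    h = 10.0 ** (-float(pH))

    def site_term(k: float, sites: int, cooperative: bool) -> float:
        if sites == 0:
            return 0.0
        kh = k * h
        if cooperative:
            u = kh**sites
            return sites * u / (1.0 + u) if np.isfinite(u) else float(sites)
        return sites * kh / (1.0 + kh)

    # d log10 P / d pH = -theta (bound-proton count); tetramer enters +, dimer -2x
    return float(
        -site_term(model.k_tet, model.m, model.coop_tet)
        + 2.0 * site_term(model.k_di, model.n, model.coop_di)
    )


def fit_linkage(
    series: PhSeries,
    m: int = 3,
    n: int = 2,
    coop_tet: bool = True,
    coop_di: bool = False,
    exclude: Sequence[int] = (),
    weighted: bool = False,
    x0: Optional[LinkageModel] = None,
    fix_L0: Optional[float] = None,
) -> tuple[LinkageModel, dict[str, float]]:
    """NLLS fit of the linkage model to a (pH, L_obs) series on the log10 scale.

    Rows flagged ``upper_limit`` (and any indices in ``exclude``) are dropped.
    Parameters are optimized as log10(L0), log10(k_tet), log10(k_di).  With
    ``weighted`` the residuals are scaled by sigma/(L ln 10) propagated from
    the L_obs standard errors.  ``fix_L0`` pins the reference-state constant
    (see :func:`fit_linkage_auto` for when this is needed).  Returns the
    fitted model and a dict of standard errors keyed ``L0``, ``k_tet``,
    ``k_di``.
    """
    use = ~series.upper_limit.copy()
    for i in exclude:
        use[i] = False
    ph = series.pH[use]
    logL = np.log10(series.L_obs[use])
    if ph.size < 4:
        raise InvalidInputError("fit_linkage: need >= 4 usable points")
    if ph.size < 3:
        raise InvalidInputError("fit_linkage: fewer points than parameters")
    if weighted and series.sigma is not None:
        w = 1.0 / (series.sigma[use] / (series.L_obs[use] * np.log(10.0)))
    else:
        w = np.ones(ph.size)

    if x0 is None:
        # high-pH plateau ~ smallest L; protonation constants near 1/[H+] range
        x0 = LinkageModel(
            L0=float(series.L_obs[use][-1]) / 10.0,
            k_tet=10.0 ** (series.pH[-1] + 0.5),
            k_di=10.0 ** (series.pH[0] + 0.5),
            m=m,
            n=n,
            coop_tet=coop_tet,
            coop_di=coop_di,
        )

    def make_model(x):
        if fix_L0 is None:
            L0, kt, kd = 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]
        else:
            L0, kt, kd = fix_L0, 10.0 ** x[0], 10.0 ** x[1]
        return LinkageModel(L0, kt, kd, m, n, coop_tet, coop_di)

    def residuals(x):
        return w * (log_L_model(make_model(x), ph) - logL)

    # wide log-space bounds keep 10**x away from under/overflow
    if fix_L0 is None:
        p0 = np.log10([x0.L0, x0.k_tet, x0.k_di])
        bounds = ([-30.0, -2.0, -2.0], [30.0, 20.0, 20.0])
    else:
        p0 = np.log10([x0.k_tet, x0.k_di])
        bounds = ([-2.0, -2.0], [20.0, 20.0])
    res = least_squares(residuals, p0, bounds=bounds, method="trf", x_scale="jac")
    model = make_model(res.x)
    npar = res.x.size
    ndof = max(ph.size - npar, 1)
    s2 = 2.0 * res.cost / ndof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        err_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        err_log = np.full(npar, np.nan)
    ln10 = np.log(10.0)
    if fix_L0 is None:
        log_errs = {"L0": err_log[0], "k_tet": err_log[1], "k_di": err_log[2]}
    else:
        log_errs = {"L0": 0.0, "k_tet": err_log[0], "k_di": err_log[1]}
    stderr = {
        "L0": model.L0 * ln10 * log_errs["L0"],
        "k_tet": model.k_tet * ln10 * log_errs["k_tet"],
        "k_di": model.k_di * ln10 * log_errs["k_di"],
        "log10_se_k_tet": float(log_errs["k_tet"]),
        "rmsd_log10": float(np.sqrt(np.mean(residuals(res.x) ** 2))),
    }
    return model, stderr


def fit_linkage_auto(
    series: PhSeries,
    m: int = 3,
    n: int = 2,
    coop_tet: bool = True,
    coop_di: bool = False,
    weighted: bool = False,
    identifiability_decades: float = 1.0,
) -> tuple[LinkageModel, dict[str, float]]:
    """Linkage fit with the unit-reference convention for a sloppy L0-k_tet pair.

    When every measured point lies on the protonation-saturated side of the
    tetramer transition, the data constrain only the product L0 * k_tet^m
    (plus k_di): the free fit has a flat ridge and the standard error of
    log10 k_tet diverges.  In that case the fit is repeated with the
    unprotonated reference constant pinned at L0 = 1 M^-1, making k_tet the
    reported, interpretable quantity (L0 itself is then a convention, not an
    estimate).  The returned dict carries ``L0_fixed`` = 1.0 when the
    convention was applied.
    """
    model, err = fit_linkage(series, m=m, n=n, coop_tet=coop_tet, coop_di=coop_di, weighted=weighted)
    if not np.isfinite(err["log10_se_k_tet"]) or err["log10_se_k_tet"] > identifiability_decades:
        model, err = fit_linkage(
            series, m=m, n=n, coop_tet=coop_tet, coop_di=coop_di, weighted=weighted, fix_L0=1.0
        )
        err = dict(err, L0_fixed=1.0)
    return model, err


def rank_site_models(
    series: PhSeries,
    site_counts: Sequence[tuple[int, int]] = ((3, 2), (2, 2), (3, 1), (4, 2), (2, 1)),
    variants: Sequence[tuple[bool, bool]] = ((True, False), (False, False), (True, True), (False, True)),
) -> list[dict]:
    """Fit all (m, n) x (coop_tet, coop_di) combinations; rank by log10 RMSD.

    Reproduces the model-comparison style of analysis on a (pH, L_obs) table.
    Combinations that fail to fit are skipped.
    """
    rows = []
    for m, n in site_counts:
        for coop_tet, coop_di in variants:
            try:
                model, err = fit_linkage(series, m=m, n=n, coop_tet=coop_tet, coop_di=coop_di)
            except (InvalidInputError, ValueError):
                continue
            rows.append(
                {
                    "m": m,
                    "n": n,
                    "coop_tet": coop_tet,
                    "coop_di": coop_di,
                    "rmsd_log10": err["rmsd_log10"],
                    "model": model,
                }
            )
    rows.sort(key=lambda r: r["rmsd_log10"])
    return rows
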