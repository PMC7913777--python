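"""Seeded synthetic-data generators emulating the study's experimental designs.

Every generator returns (data, truth) where ``truth`` records the generating
parameters and the seed, so each fitting stage has ground-truth inputs.  One
fixture seed drives all noise draws through ``numpy.random.SeedSequence``
spawning keyed by scan index, so adding scans to a design does not shift the
draws of earlier scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq

from . import itc as itc_mod
from . import svel
from .hydro import BufferState, InvalidInputError, glycerol_buffer_properties
from .sedeq import SEModelSpec, SEScan, se_exponent
from .svel import CellGeometry, SVScanSet

__all__ = [
    "FixtureSpec",
    "btp_buffer",
    "gen_se",
    "gen_sv",
    "gen_itc",
    "load_fixture",
]


def btp_buffer(pH: float = 8.0, temperature: float = 298.15) -> BufferState:
    """Working buffer: 25 % v/v glycerol, 50 mM NaCl, properties from the table."""
    rho, eta = glycerol_buffer_properties(25.0, temperature, nacl_molar=0.05)
    return BufferState(density=rho, viscosity=eta, temperature=temperature, pH=pH, label="BTP")


@dataclass
class FixtureSpec:
    """One synthetic experiment: kind ('SE' | 'SV' | 'ITC'), truth, design, noise, seed."""

    kind: str
    truth: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("SE", "SV", "ITC"):
            raise InvalidInputError(f"FixtureSpec: unknown kind {self.kind!r}")


def _child_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


# ---------------------------------------------------------------------------
# Sedimentation equilibrium
# ---------------------------------------------------------------------------

#: default SE design mirroring the dimer-tetramer study conditions
SE_DEFAULT_DESIGN = {
    "loadings_uM_monomer": [4.0, 8.0, 12.0],
    "speeds_rpm": [20000.0, 25000.0, 30000.0],
    "column_length_cm": 0.3,
    "first_meniscus_cm": 6.0,
    "channel_spacing_cm": 0.4,
    "radial_step_cm": 0.003,
    "pH": 8.0,
}

SE_DEFAULT_TRUTH = {
    "L_obs": 2.16e5,
    "dimer_mass_kDa": 43.9,
    "vbar_ml_g": 0.711,
    "eps_per_dimer": 2 * 5.3e4,
    "pathlength_cm": 1.2,
}


def _meniscus_amplitude(L: float, R_tot_dimer: float, phi: np.ndarray, radii: np.ndarray) -> float:
    """Dimer concentration at the meniscus giving a column-average loading R_tot.

    Conservation over the sector column: the radial average (r-weighted) of
    total dimer-equivalents 2*c2 + ... must equal the loading.
    """

    def loading_error(c2m: float) -> float:
        c2 = c2m * np.exp(phi)
        tot = c2 + 2.0 * L * c2**2  # dimer-equivalents
        avg = np.trapezoid(tot * radii, radii) / np.trapezoid(radii, radii)
        return avg - R_tot_dimer

    hi = R_tot_dimer
    while loading_error(hi) < 0:
        hi *= 2.0
    return brentq(loading_error, 0.0, hi, rtol=8.9e-16)


def gen_se(fixture: FixtureSpec) -> tuple[list[SEScan], dict]:
    """Synthetic dimer-tetramer SE scans over a loadings x speeds design.

    Each loading occupies its own short channel; the amplitude at each
    speed conserves the loading over the column, emulating equilibrium
    attained from a uniformly filled channel.  Gaussian noise of
    ``fixture.noise_sd`` AU is added per scan (seed-split by scan index).
    """
    if fixture.kind != "SE":
        raise InvalidInputError("gen_se: fixture kind must be 'SE'")
    design = {**SE_DEFAULT_DESIGN, **fixture.design}
    truth = {**SE_DEFAULT_TRUTH, **fixture.truth}
    buffer = btp_buffer(pH=design["pH"])
    L = truth["L_obs"]
    signal_coeff = truth["eps_per_dimer"] * truth["pathlength_cm"]

    scans: list[SEScan] = []
    idx = 0
    for ch, loading in enumerate(design["loadings_uM_monomer"]):
        men = design["first_meniscus_cm"] + ch * design["channel_spacing_cm"]
        bot = men + design["column_length_cm"]
        radii = np.arange(men + 0.006, bot - 0.003, design["radial_step_cm"])
        R_tot_dimer = loading * 1e-6 / 2.0
        for rpm in design["speeds_rpm"]:
            phi = se_exponent(truth["dimer_mass_kDa"], truth["vbar_ml_g"], buffer, rpm, radii, men)
            c2m = _meniscus_amplitude(L, R_tot_dimer, phi, radii)
            c2 = c2m * np.exp(phi)
            a = signal_coeff * (c2 + 2.0 * L * c2**2)
            if fixture.noise_sd > 0:
                a = a + _child_rng(fixture.seed, idx).normal(0.0, fixture.noise_sd, a.size)
            scans.append(
                SEScan(
                    radii=radii,
                    absorbance=a,
                    rotor_speed=rpm,
                    channel=f"ch{ch}",
                    meniscus=men,
                    bottom=bot,
                )
            )
            idx += 1

    record = {
        "kind": "SE",
        "seed": fixture.seed,
        "noise_sd": fixture.noise_sd,
        "truth": truth,
        "design": design,
    }
    return scans, record


def se_model_spec_for(truth: Optional[dict] = None, L_guess: float = 1e5) -> SEModelSpec:
    """A dimer-tetramer fit spec matching the generator's signal convention."""
    t = {**SE_DEFAULT_TRUTH, **(truth or {})}
    return SEModelSpec(
        mode="dimer-tetramer",
        dimer_mass=t["dimer_mass_kDa"],
        dimer_vbar=t["vbar_ml_g"],
        L_obs=L_guess,
        signal_coeff=t["eps_per_dimer"] * t["pathlength_cm"],
    )


# ---------------------------------------------------------------------------
# Sedimentation velocity
# ---------------------------------------------------------------------------

SV_DEFAULT_DESIGN = {
    "O_total_uM": 1.5,
    "ratio_R_to_O": 6.0,  # RecR monomers per RecO
    "n_scans": 60,
    "scan_interval_s": 60.0,
    "rotor_speed_rpm": 42000.0,
    "meniscus_cm": 6.14,
    "bottom_cm": 7.2,
    "pathlength_cm": 1.2,
    "n_radial": 400,
    "pH": 8.0,
}


def gen_sv(
    fixture: FixtureSpec, network: Optional[svel.ReactionNetwork] = None
) -> tuple[SVScanSet, dict]:
    """Synthetic reacting-system velocity scans (Scheme of the RecOR system).

    ``fixture.truth`` may carry ``variant`` ('no_p15' | 'plus_p15') and
    overrides for the equilibrium constants; noise of ``noise_sd`` AU
    (default 0.005 in the shipped fixtures) is seeded from the fixture seed.
    """
    if fixture.kind != "SV":
        raise InvalidInputError("gen_sv: fixture kind must be 'SV'")
    design = {**SV_DEFAULT_DESIGN, **fixture.design}
    if network is None:
        variant = fixture.truth.get("variant", "no_p15")
        overrides = {
            k: fixture.truth[k] for k in ("L_obs", "K2", "K3", "K4") if k in fixture.truth
        }
        network = svel.default_network(variant, **overrides)
    geometry = CellGeometry(
        meniscus=design["meniscus_cm"],
        bottom=design["bottom_cm"],
        rotor_speed=design["rotor_speed_rpm"],
        pathlength=design["pathlength_cm"],
        n_radial=design["n_radial"],
    )
    times = np.arange(1, design["n_scans"] + 1) * design["scan_interval_s"]
    O_tot = design["O_total_uM"] * 1e-6
    R_tot = O_tot * design["ratio_R_to_O"]
    buffer = btp_buffer(pH=design["pH"])
    scans = svel.simulate_lamm(network, (O_tot, R_tot), geometry, times, buffer)
    if fixture.noise_sd > 0:
        child = np.random.SeedSequence(entropy=fixture.seed, spawn_key=(0,))
        scans = svel.add_noise(scans, fixture.noise_sd, seed=child.generate_state(1)[0] % (2**31))
    record = {
        "kind": "SV",
        "seed": fixture.seed,
        "noise_sd": fixture.noise_sd,
        "truth": {
            "L_obs": network.L_obs,
            "K2": network.K2,
            "K3": network.K3,
            "K4": network.K4,
            "k_off": list(network.k_off),
        },
        "design": design,
    }
    return scans, record


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

ITC_DEFAULT_DESIGN = {
    "n_injections": 28,
    "injection_volume_ul": 10.0,
    "syringe_uM": 50.0,
    "cell_uM": 2.0,
    "V0_ml": 1.4,
    "blank_heat_ucal": -0.05,
    # blank heats ship smoothed (dilution model), so no noise by default
    "blank_noise_sd": 0.0,
}

ITC_DEFAULT_TRUTH = {"n": 1.0, "K_obs": 1.2e7, "dH_obs": -5.2}

#: apparent-parameter attenuation for titrating P15 into RecO pre-mixed with
#: excess RecR: binding is weakened and the observed enthalpy falls below
#: 1 kcal/mol (near the detection limit) — reproduced qualitatively only
RECR_COMPETITION_ATTENUATION = {"K_factor": 0.05, "dH_obs": -0.8}


def gen_itc(fixture: FixtureSpec) -> tuple[itc_mod.Titration, dict]:
    """Synthetic titration: model heats plus noise, and a dilution-only blank."""
    if fixture.kind != "ITC":
        raise InvalidInputError("gen_itc: fixture kind must be 'ITC'")
    design = {**ITC_DEFAULT_DESIGN, **fixture.design}
    truth = {**ITC_DEFAULT_TRUTH, **fixture.truth}
    if design.get("recr_competition"):
        truth = dict(
            truth,
            K_obs=truth["K_obs"] * RECR_COMPETITION_ATTENUATION["K_factor"],
            dH_obs=RECR_COMPETITION_ATTENUATION["dH_obs"],
        )
    model = itc_mod.ITCModel(
        n=truth["n"], K_obs=truth["K_obs"], dH_obs=truth["dH_obs"], V0=design["V0_ml"]
    )
    titration = itc_mod.Titration(
        injection_volumes=np.full(design["n_injections"], design["injection_volume_ul"]),
        syringe_conc=design["syringe_uM"] * 1e-6,
        cell_conc=design["cell_uM"] * 1e-6,
        V0=design["V0_ml"],
    )
    clean = itc_mod.predict_differential_heats(titration, model)
    blank_level = design["blank_heat_ucal"]
    rng_sig = _child_rng(fixture.seed, 0)
    rng_blk = _child_rng(fixture.seed, 1)
    noise = fixture.noise_sd
    blank_noise = design["blank_noise_sd"]
    titration.heats = clean + blank_level + (
        rng_sig.normal(0.0, noise, clean.size) if noise > 0 else 0.0
    )
    titration.blank_heats = np.full(clean.size, blank_level) + (
        rng_blk.normal(0.0, blank_noise, clean.size) if blank_noise > 0 else 0.0
    )
    record = {
        "kind": "ITC",
        "seed": fixture.seed,
        "noise_sd": noise,
        "truth": truth,
        "design": design,
    }
    return titration, record


# ---------------------------------------------------------------------------
# Fixture YAML library
# ---------------------------------------------------------------------------


def load_fixture(name_or_path: str) -> FixtureSpec:
    """Load a FixtureSpec from a YAML file or a shipped fixture name.

    Shipped fixtures live in ``assemblink/fixtures/paper/`` and are addressed
    by bare name, e.g. ``"recr_ph8_se"``.
    """
    import os

    if os.path.exists(name_or_path):
        with open(name_or_path) as fh:
            raw = yaml.safe_load(fh)
    else:
        ref = resources.files("assemblink") / "fixtures" / "paper" / f"{name_or_path}.yaml"
        raw = yaml.safe_load(ref.read_text())

    def coerce(d):
        # YAML 1.1 reads exponent floats without a sign ("1.2e7") as strings
        out = {}
        for k, v in d.items():
            if isinstance(v, str):
                try:
                    v = float(v)
                except ValueError:
                    pass
            out[k] = v
        return out

    return FixtureSpec(
        kind=raw["kind"],
        truth=coerce(raw.get("truth", {})),
        design=coerce(raw.get("design", {})),
        noise_sd=float(raw.get("noise_sd", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
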