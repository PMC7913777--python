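"""Readers and writers for scan CSVs, pH-series tables, result JSON, run logs.

Scan dialect: ``#``-prefixed header lines carrying metadata, then
``radius_cm,absorbance`` rows::

    # rotor_rpm: 25000
    # wavelength_nm: 230
    # channel: ch0
    # meniscus_cm: 6.0
    # bottom_cm: 6.3
    radius_cm,absorbance
    6.0100,0.1234567890

Velocity scans add ``# time_s:``.  All files are UTF-8 with LF endings;
floats are written with 12 significant digits so a write/read/write cycle is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .hydro import InvalidInputError
from .linkage import PhSeries
from .sedeq import SEScan

__all__ = [
    "SCHEMA_VERSION",
    "read_scan_csv",
    "write_scan_csv",
    "read_ph_series_csv",
    "write_result_json",
    "read_result_json",
    "append_run_log",
]

SCHEMA_VERSION = "1.0"

_REQUIRED_KEYS = ("rotor_rpm", "wavelength_nm", "channel", "meniscus_cm", "bottom_cm")


class ScanParseError(InvalidInputError):
    """A scan file does not match the dialect; names the offending key."""


def _fmt(x: float) -> str:
    return f"{float(x):.12g}"


@dataclass
class RawScan:
    """A parsed scan file: metadata plus the radial trace."""

    radii: np.ndarray
    absorbance: np.ndarray
    rotor_rpm: float
    wavelength_nm: float
    channel: str
    meniscus_cm: float
    bottom_cm: float
    time_s: Optional[float] = None

    def to_se_scan(self) -> SEScan:
        return SEScan(
            radii=self.radii,
            absorbance=self.absorbance,
            rotor_speed=self.rotor_rpm,
            wavelength=self.wavelength_nm,
            channel=self.channel,
            meniscus=self.meniscus_cm,
            bottom=self.bottom_cm,
        )


def read_scan_csv(path: str) -> RawScan:
    """Parse one scan file; raises :class:`ScanParseError` naming missing keys."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line.startswith("radius_cm"):
                continue
            else:
                if "," in line:
                    a, _, b = line.partition(",")
                else:
                    # best-effort shim for whitespace-delimited XL-A exports
                    parts = line.split()
                    if len(parts) < 2:
                        raise ScanParseError(f"{path}: unparseable data row {line!r}")
                    a, b = parts[0], parts[1]
                rows.append((float(a), float(b)))
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ScanParseError(f"{path}: missing required header key '# {key}:'")
    radii = np.array([r for r, _ in rows])
    if np.any(np.diff(radii) <= 0):
        raise ScanParseError(f"{path}: radii must be strictly increasing")
    return RawScan(
        radii=radii,
        absorbance=np.array([a for _, a in rows]),
        rotor_rpm=float(meta["rotor_rpm"]),
        wavelength_nm=float(meta["wavelength_nm"]),
        channel=meta["channel"],
        meniscus_cm=float(meta["meniscus_cm"]),
        bottom_cm=float(meta["bottom_cm"]),
        time_s=float(meta["time_s"]) if "time_s" in meta else None,
    )


def write_scan_csv(scan: RawScan | SEScan, path: str, time_s: Optional[float] = None) -> None:
    """Write one scan in the canonical dialect (UTF-8, LF)."""
    if isinstance(scan, SEScan):
        scan = RawScan(
            radii=scan.radii,
            absorbance=scan.absorbance,
            rotor_rpm=scan.rotor_speed,
            wavelength_nm=scan.wavelength,
            channel=scan.channel,
            meniscus_cm=scan.meniscus,
            bottom_cm=scan.bottom,
            time_s=time_s,
        )
    lines = [
        f"# rotor_rpm: {_fmt(scan.rotor_rpm)}",
        f"# wavelength_nm: {_fmt(scan.wavelength_nm)}",
        f"# channel: {scan.channel}",
        f"# meniscus_cm: {_fmt(scan.meniscus_cm)}",
        f"# bottom_cm: {_fmt(scan.bottom_cm)}",
    ]
    if scan.time_s is not None:
        lines.append(f"# time_s: {_fmt(scan.time_s)}")
    lines.append("radius_cm,absorbance")
    lines.extend(f"{_fmt(r)},{_fmt(a)}" for r, a in zip(scan.radii, scan.absorbance))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_ph_series_csv(path: str) -> PhSeries:
    """Read a ``pH,L_obs,SE,upper_limit`` table into a :class:`PhSeries`."""
    df = pd.read_csv(path, comment="#")
    sigma = df["SE"].to_numpy(dtype=float) if "SE" in df else None
    upper = (
        df["upper_limit"].fillna(0).to_numpy(dtype=float).astype(bool)
        if "upper_limit" in df
        else None
    )
    return PhSeries(pH=df["pH"].to_numpy(), L_obs=df["L_obs"].to_numpy(), sigma=sigma, upper_limit=upper)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(v, sig) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_result_json(result: dict, path: str) -> None:
    """Serialize a result dict (schema-versioned, floats to 12 significant digits)."""
    payload = {"schema_version": SCHEMA_VERSION, **_round_floats(result)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result_json(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def append_run_log(out_dir: str, command: str, config: dict, extra: Optional[dict] = None) -> None:
    """Append one machine-readable JSON line recording a run."""
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(_round_floats(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    entry = {
        "command": command,
        "version": __version__,
        "config_hash": cfg_hash,
        **(extra or {}),
    }
    with open(os.path.join(out_dir, "run_log.jsonl"), "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
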