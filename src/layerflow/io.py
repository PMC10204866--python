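"""CSV file formats for FD-DOS and DCS measurements.

FD-DOS tables hold one multidistance measurement:

    # meta: {"modulation_frequency_hz": 110000000.0, ...}
    rho_cm,amplitude,phase_deg
    0.8,1.23e-03,12.71
    ...

DCS tables hold one curve per (distance, integration time):

    # meta: {"rho_cm": 2.5, "wavelength_cm": 7.85e-05, "integration_time_s": 10.0}
    tau_s,g2
    6e-07,1.4993
    ...

Metadata travels in a single JSON header comment (``# meta: {...}``); extra
keys (seed, config hash) are preserved on round trip.  Phases are stored in
degrees on disk and radians in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DcsData, FddosData

__all__ = [
    "FormatError",
    "read_fddos_table",
    "write_fddos_table",
    "read_dcs_table",
    "write_dcs_table",
]

_META_PREFIX = "# meta:"


class FormatError(ValueError):
    """Raised for malformed measurement tables."""


def _read_with_meta(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith(_META_PREFIX):
            try:
                meta.update(json.loads(line[len(_META_PREFIX):]))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid metadata header: {exc}") from exc
        elif line.strip() and not line.startswith("#"):
            body.append(line)
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(body)))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    return df, meta


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_META_PREFIX + " " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_fddos_table(path) -> FddosData:
    """Read a multidistance FD-DOS table; phases converted to radians."""
    df, meta = _read_with_meta(path)
    required = {"rho_cm", "amplitude", "phase_deg"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "modulation_frequency_hz" not in meta:
        raise FormatError(f"{path}: metadata lacks modulation_frequency_hz")
    bad = df.index[df["amplitude"] <= 0]
    if len(bad):
        raise FormatError(f"{path}: non-positive amplitude in row {bad[0] + 1}")
    dup = df.index[df["rho_cm"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate distance in row {dup[0] + 1}")
    df = df.sort_values("rho_cm")
    return FddosData(
        distances=df["rho_cm"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
        phases=np.deg2rad(df["phase_deg"].to_numpy()),
        modulation_frequency=float(meta["modulation_frequency_hz"]),
    )


def write_fddos_table(path, data: FddosData, extra_meta: dict | None = None) -> None:
    meta = {"modulation_frequency_hz": data.modulation_frequency}
    meta.update(extra_meta or {})
    df = pd.DataFrame({
        "rho_cm": data.distances,
        "amplitude": data.amplitudes,
        "phase_deg": np.rad2deg(data.phases),
    })
    _write_with_meta(path, df, meta)


def read_dcs_table(path) -> DcsData:
    """Read a single-distance DCS autocorrelation table."""
    df, meta = _read_with_meta(path)
    required = {"tau_s", "g2"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    for key in ("rho_cm", "wavelength_cm"):
        if key not in meta:
            raise FormatError(f"{path}: metadata lacks {key}")
    taus = df["tau_s"].to_numpy()
    if np.any(np.diff(taus) <= 0):
        row = int(np.argmax(np.diff(taus) <= 0)) + 2
        raise FormatError(f"{path}: delay times not increasing at row {row}")
    return DcsData(
        distance=float(meta["rho_cm"]),
        taus=taus,
        g2=df["g2"].to_numpy(),
        wavelength=float(meta["wavelength_cm"]),
        integration_time=float(meta.get("integration_time_s", 10.0)),
    )


def write_dcs_table(path, data: DcsData, extra_meta: dict | None = None) -> None:
    meta = {
        "rho_cm": data.distance,
        "wavelength_cm": data.wavelength,
        "integration_time_s": data.integration_time,
    }
    meta.update(extra_meta or {})
    df = pd.DataFrame({"tau_s": data.taus, "g2": data.g2})
    _write_with_meta(path, df, meta)
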