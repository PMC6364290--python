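"""Dissolved-oxygen unit conversions.

Concentration units (mg/L, µg/L, mmol/L, µmol/L, mL/L) interconvert through
the molar mass of O2.  Partial-pressure and saturation units (%air, %O2,
mmHg, torr, kPa, hPa) additionally require the water conditions, because the
bridge between pressure and concentration is the solubility of oxygen at
100% air saturation.

The solubility model is the combined fit of García & Gordon (1992) to the
Benson–Krause data, which is the standard model used by oceanographic and
respirometry software.  Barometric pressures other than 1 atm are handled by
scaling the saturation concentration with (P - p_w) / (1 - p_w), where p_w
is the vapour pressure of water at the given temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterConditions",
    "SUPPORTED_UNITS",
    "canonical_unit",
    "o2_saturation_concentration",
    "water_vapour_pressure",
    "convert_do",
    "convert_file",
]

# Pinned physical constants (bit-reproducibility matters more than the last
# digit of CODATA here).
O2_MOLAR_MASS = 31.9988        # g/mol
O2_MOLAR_VOLUME = 22.3916      # L/mol at STP, for mL/L <-> mg/L
O2_FRACTION_DRY_AIR = 0.20946  # mole fraction of O2 in dry air
ATM_MMHG = 760.0
ATM_KPA = 101.325

# García & Gordon (1992) "combined fit" coefficients; ln(C) in mL/L.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7

# Canonical unit labels and their accepted spellings (matched after
# lowercasing and stripping spaces).
_CANONICAL = {
    "mg/L": ["mg/l", "mgo2/l", "mg o2/l", "mgo₂/l"],
    "ug/L": ["ug/l", "µg/l", "μg/l", "ugo2/l"],
    "mmol/L": ["mmol/l", "mmolo2/l"],
    "umol/L": ["umol/l", "µmol/l", "μmol/l", "umolo2/l"],
    "mL/L": ["ml/l", "mlo2/l"],
    "%air": ["%air", "%airsaturation", "%airsat", "%sat", "percentairsaturation", "airsat%"],
    "%O2": ["%o2", "%oxygen", "%o₂"],
    "mmHg": ["mmhg"],
    "torr": ["torr"],
    "kPa": ["kpa"],
    "hPa": ["hpa"],
}
_ALIASES = {alias: canon for canon, aliases in _CANONICAL.items() for alias in aliases}

SUPPORTED_UNITS = tuple(_CANONICAL)

_PRESSURE_LIKE = {"%air", "%O2", "mmHg", "torr", "kPa", "hPa"}


class UnitError(ValueError):
    """Unknown unit label or conversion lacking required conditions."""


def canonical_unit(label: str) -> str:
    """Resolve a unit label (case-insensitive, synonym-tolerant) to its canonical form."""
    key = label.strip().lower().replace(" ", "")
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnitError(
            f"unknown DO unit {label!r}; supported: {', '.join(SUPPORTED_UNITS)}"
        ) from None


@dataclass(frozen=True)
class WaterConditions:
    """Temperature (°C), practical salinity and barometric pressure (atm)."""

    temperature: float
    salinity: float = 0.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature <= 40.0):
            raise ValueError(f"temperature {self.temperature} °C outside [0, 40]")
        if self.salinity < 0:
            raise ValueError("salinity must be >= 0")
        if not self.pressure > 0:
            raise ValueError("pressure must be > 0 atm")


def water_vapour_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water in atm (Antoine equation)."""
    mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + temperature))
    return mmhg / ATM_MMHG


def o2_saturation_concentration(cond: WaterConditions) -> float:
    """O2 concentration (mg/L) at 100% air saturation under the given conditions.

    Strictly decreasing in temperature and salinity; linear in the dry-air
    partial pressure (P - p_w).
    """
    t, s = cond.temperature, cond.salinity
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += s * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * s * s
    ml_per_l = math.exp(ln_c)
    mg_per_l = ml_per_l * O2_MOLAR_MASS / O2_MOLAR_VOLUME
    pw = water_vapour_pressure(t)
    return mg_per_l * (cond.pressure - pw) / (1.0 - pw)


def _to_mg_l(value, unit: str, cond: WaterConditions | None):
    if unit == "mg/L":
        return value
    if unit == "ug/L":
        return np.asarray(value) / 1000.0 if np.ndim(value) else value / 1000.0
    if unit == "mmol/L":
        return value * O2_MOLAR_MASS
    if unit == "umol/L":
        return value * O2_MOLAR_MASS / 1000.0
    if unit == "mL/L":
        return value * O2_MOLAR_MASS / O2_MOLAR_VOLUME
    if cond is None:
        raise UnitError(f"conversion from {unit} requires water conditions")
    sat = o2_saturation_concentration(cond)
    if unit == "%air":
        return value / 100.0 * sat
    # remaining units go through the O2 partial pressure in atm
    pw = water_vapour_pressure(cond.temperature)
    po2_at_sat = O2_FRACTION_DRY_AIR * (cond.pressure - pw)
    if unit == "%O2":
        po2 = value / 100.0 * cond.pressure
    elif unit in ("mmHg", "torr"):
        po2 = value / ATM_MMHG
    elif unit == "kPa":
        po2 = value / ATM_KPA
    elif unit == "hPa":
        po2 = value / (ATM_KPA * 10.0)
    else:  # pragma: no cover - guarded by canonical_unit
        raise UnitError(f"unknown unit {unit}")
    return po2 / po2_at_sat * sat


def _from_mg_l(value, unit: str, cond: WaterConditions | None):
    if unit == "mg/L":
        return value
    if unit == "ug/L":
        return value * 1000.0
    if unit == "mmol/L":
        return value / O2_MOLAR_MASS
    if unit == "umol/L":
        return value / O2_MOLAR_MASS * 1000.0
    if unit == "mL/L":
        return value * O2_MOLAR_VOLUME / O2_MOLAR_MASS
    if cond is None:
        raise UnitError(f"conversion to {unit} requires water conditions")
    sat = o2_saturation_concentration(cond)
    frac = value / sat  # fraction of air saturation
    if unit == "%air":
        return frac * 100.0
    pw = water_vapour_pressure(cond.temperature)
    po2 = frac * O2_FRACTION_DRY_AIR * (cond.pressure - pw)
    if unit == "%O2":
        return po2 / cond.pressure * 100.0
    if unit in ("mmHg", "torr"):
        return po2 * ATM_MMHG
    if unit == "kPa":
        return po2 * ATM_KPA
    if unit == "hPa":
        return po2 * ATM_KPA * 10.0
    raise UnitError(f"unknown unit {unit}")  # pragma: no cover


def convert_do(value, from_unit: str, to_unit: str, cond: WaterConditions | None = None):
    """Convert a DO reading (scalar or array) between units.

    ``cond`` is required whenever either side is a saturation or
    partial-pressure unit.  Round trips recover the input to floating-point
    precision because every conversion routes through mg/L.
    """
    f, t = canonical_unit(from_unit), canonical_unit(to_unit)
    if f == t:
        return value
    return _from_mg_l(_to_mg_l(value, f, cond), t, cond)


def convert_file(
    path,
    out_path,
    from_unit: str,
    to_unit: str,
    salinity: float = 0.0,
    pressure: float = 1.0,
):
    """Convert the O2 columns of a generic-format logger file between units.

    Each row is converted under its own temperature (with the supplied
    salinity and barometric pressure), so saturation-based conversions track
    temperature drift.  Only O2 columns change; timestamps, phase labels and
    temperatures are passed through unaltered.
    """
    from .logger_io import read_generic, write_generic  # local import: avoids cycle

    f, t = canonical_unit(from_unit), canonical_unit(to_unit)
    df, o2_cols = read_generic(path)
    if f == t:
        write_generic(df, o2_cols, out_path)
        return out_path
    needs_cond = f in _PRESSURE_LIKE or t in _PRESSURE_LIKE
    for col in o2_cols:
        if needs_cond:
            df[col] = [
                convert_do(v, f, t, WaterConditions(temp, salinity, pressure))
                for v, temp in zip(df[col].to_numpy(), df["temp"].to_numpy())
            ]
        else:
            df[col] = convert_do(df[col].to_numpy(), f, t)
    write_generic(df, o2_cols, out_path)
    return out_path
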