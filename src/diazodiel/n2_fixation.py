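"""Acetylene reduction assay → N₂ fixation rates and nitrogenase e⁻ demand.

Nitrogenase reduces acetylene to ethylene; headspace ethylene accumulation
over a short dark incubation, converted to moles with the ideal-gas law, is
a proxy for nitrogenase activity. The theoretical molar ratio of acetylene
reduction to cellular N₂ reduction is 4:1, and fixing one N₂ costs 8
electrons, which links the nocturnal fixation budget back to the
photosynthetic electron transport budget of the preceding light phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError, UndefinedRatioError

__all__ = [
    "AraVial",
    "ConversionConstants",
    "ethylene_production_rate",
    "n2_rate",
    "electron_demand",
    "electron_fraction",
    "read_ara_table",
]

#: Ideal gas constant, L·atm·mol⁻¹·K⁻¹.
R_L_ATM = 0.08206


@dataclass(frozen=True)
class ConversionConstants:
    """Stoichiometric constants of the assay.

    ara_ratio: mol C₂H₄ produced per mol N₂ that would have been reduced
    (theoretical 4:1). electrons_per_n2: electrons consumed by nitrogenase
    per N₂ fixed (8: six for the reduction plus obligatory H₂ evolution).
    """

    ara_ratio: float = 4.0
    electrons_per_n2: float = 8.0

    def __post_init__(self) -> None:
        if not (self.ara_ratio > 0 and self.electrons_per_n2 > 0):
            raise DomainError("conversion constants must be positive")


@dataclass(frozen=True)
class AraVial:
    """One sealed assay vial: headspace ethylene before/after incubation.

    c2h4_t0 / c2h4_t1 in ppm (v/v); volumes in mL; t_inc in h; chl in
    µg Chl a mL⁻¹ of the liquid sample; temperature in °C, pressure in atm.
    """

    c2h4_t0: float
    c2h4_t1: float
    headspace_vol: float
    sample_vol: float
    t_inc: float
    chl: float
    temperature: float = 28.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        for name in ("headspace_vol", "sample_vol", "t_inc", "chl", "pressure"):
            v = getattr(self, name)
            if not v > 0:
                raise DomainError(f"{name} must be positive, got {v}")
        if self.c2h4_t0 < 0 or self.c2h4_t1 < 0:
            raise DomainError("ethylene mixing ratios must be >= 0")
        if self.temperature <= -273.15:
            raise DomainError("temperature below absolute zero")


def ethylene_production_rate(v: AraVial) -> float:
    """Ethylene production, nmol C₂H₄ (µg Chl a)⁻¹ h⁻¹.

    Headspace-only accounting: Δppm → moles via n = x·P·V/(R·T) at the vial
    temperature and pressure, then per incubation hour and per total µg Chl
    in the liquid sample. A negative Δppm clamps to zero with a warning.
    """
    dppm = v.c2h4_t1 - v.c2h4_t0
    if dppm < 0:
        warnings.warn(
            f"ethylene decreased by {-dppm} ppm during incubation; "
            "clamping production to zero",
            stacklevel=2,
        )
        dppm = 0.0
    t_kelvin = v.temperature + 273.15
    headspace_l = v.headspace_vol / 1000.0
    mol = dppm * 1e-6 * v.pressure * headspace_l / (R_L_ATM * t_kelvin)
    nmol = mol * 1e9
    chl_total = v.chl * v.sample_vol
    return nmol / v.t_inc / chl_total


def n2_rate(ethylene_rate: float, k: ConversionConstants = ConversionConstants()) -> float:
    """N₂ fixation rate from an ethylene production rate (same Chl/h units)."""
    if ethylene_rate < 0:
        raise DomainError(f"ethylene rate must be >= 0, got {ethylene_rate}")
    return ethylene_rate / k.ara_ratio


def electron_demand(
    daily_n2: float, k: ConversionConstants = ConversionConstants()
) -> float:
    """Electrons required to fix ``daily_n2`` (µmol e⁻ per µmol N₂ × amount)."""
    if daily_n2 < 0:
        raise DomainError(f"N2 amount must be >= 0, got {daily_n2}")
    return k.electrons_per_n2 * daily_n2


def electron_fraction(demand: float, etr_integral: float) -> float:
    """Percentage of transported electrons devoted to N₂ fixation."""
    if etr_integral <= 0:
        raise UndefinedRatioError(
            f"electron transport integral must be positive, got {etr_integral}"
        )
    return 100.0 * demand / etr_integral


def read_ara_table(path: str | Path) -> pd.DataFrame:
    """Read ``ara.csv`` (vial, t0_ppm, t1_ppm, dt_h, headspace_ml, sample_ml).

    The ``vial`` column encodes the sampling hour-of-day as a number.
    """
    df = pd.read_csv(path)
    missing = {"vial", "t0_ppm", "t1_ppm", "dt_h", "headspace_ml",
               "sample_ml"} - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    return df
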