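"""Species physiology summaries: OD normalization, Φ ratios, comparisons.

Assembles the phase-integrated rates of the upstream stages into one record
per species and derives the headline statistics: the electron demand for
carbon fixation at saturating light (Φ_max = ETR_max / P_m^B) and under
light limitation (Φ_lim = α^ETR / α^C), light-phase respiration as a
percentage of gross O₂ evolution, and cross-species fold ratios.

Reporting convention: ratios to 1 decimal, percentages to integers,
electron amounts to 2 decimals — raw unrounded values are always retained
alongside the rounded forms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import NormalizationAnchorError, UndefinedRatioError

__all__ = [
    "SpeciesPhysiology",
    "normalize_od",
    "phi_max",
    "phi_lim",
    "respiration_fraction",
    "cross_species_ratios",
    "write_summary_table",
    "read_summary_table",
]

#: Hour used as the OD normalization anchor (1 h after light onset, "1L").
OD_ANCHOR_HOUR = 1.0


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Phase-integrated rates and derived budget statistics for one species.

    Amount fields are per 12-h phase in Chl-normalized units:
    O₂ and respiration in µmol O₂ (µg Chl)⁻¹ 12 h⁻¹, N₂ in
    µmol N₂ (µg Chl)⁻¹ 12 h⁻¹, electron amounts in µmol e⁻ (µg Chl)⁻¹
    12 h⁻¹. Hourly maxima (``etr_max_h``, ``pmB_h``) are per hour.
    """

    species: str
    ek_c: float
    etr_max_h: float
    etr_max_12h: float
    etr_at_growth_irradiance: float
    o2_day: float
    o2_night: float
    resp_day: float
    resp_night: float
    pmB_h: float
    pmB_12h: float
    n2_day: float
    n2_night: float
    e_demand: float
    electron_pct: float
    phi_max: float
    phi_lim: float
    alpha_etr: float = float("nan")
    alpha_c: float = float("nan")

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def normalize_od(t_h, od, anchor: float = OD_ANCHOR_HOUR) -> np.ndarray:
    """Normalize an OD₇₃₅ series to its value at the 1L anchor.

    The anchor value is linearly interpolated; the normalized series is
    exactly 1 at the anchor. The series must bracket the anchor hour.
    """
    t = np.asarray(t_h, dtype=float)
    v = np.asarray(od, dtype=float)
    if t.size == 0 or t.min() > anchor or t.max() < anchor:
        raise NormalizationAnchorError(
            f"OD series [{t.min() if t.size else '∅'}, "
            f"{t.max() if t.size else '∅'}] does not cover the "
            f"{anchor} h anchor"
        )
    ref = float(np.interp(anchor, t, v))
    if ref <= 0:
        raise NormalizationAnchorError(f"anchor OD must be positive, got {ref}")
    return v / ref


def phi_max(etr_max: float, pmB: float) -> float:
    """Electron demand per fixed C at saturating light (e⁻ C⁻¹).

    Both rates must be in the same per-hour (or per-phase) convention.
    """
    if pmB <= 0:
        raise UndefinedRatioError(f"pmB must be positive, got {pmB}")
    return etr_max / pmB


def phi_lim(alpha_etr: float, alpha_c: float) -> float:
    """Electron demand per fixed C under light limitation (e⁻ C⁻¹)."""
    if alpha_c <= 0:
        raise UndefinedRatioError(f"alpha_c must be positive, got {alpha_c}")
    return alpha_etr / alpha_c


def respiration_fraction(resp_phase: float, gross_phase: float) -> float:
    """Respiration as a raw percentage of gross O₂ evolution in a phase.

    Reporting rounds to integer percent; the raw value is returned here.
    """
    if gross_phase <= 0:
        raise UndefinedRatioError(
            f"gross O2 evolution must be positive, got {gross_phase}"
        )
    return 100.0 * resp_phase / gross_phase


def cross_species_ratios(
    a: SpeciesPhysiology, b: SpeciesPhysiology
) -> dict[str, Any]:
    """Cross-species comparison record (a relative to b and vice versa).

    * ``light_resp_fold``: light-phase respiration of b over a.
    * ``total_resp_fold``: (day+night) respiration of b over a.
    * ``n2_fixation_pct``: daily N₂ fixed by a as a percentage of b's.

    Raw values are emitted together with rounded forms (folds to 1 decimal,
    percentages to the nearest integer).
    """
    def _safe_div(num: float, den: float, what: str) -> float:
        if den == 0:
            raise UndefinedRatioError(f"{what}: zero denominator")
        return num / den

    light_fold = _safe_div(b.resp_day, a.resp_day, "light-phase respiration fold")
    total_fold = _safe_div(
        b.resp_day + b.resp_night, a.resp_day + a.resp_night,
        "total respiration fold",
    )
    n2_pct = 100.0 * _safe_div(
        a.n2_day + a.n2_night, b.n2_day + b.n2_night, "daily N2 percentage"
    )
    return {
        "species_a": a.species,
        "species_b": b.species,
        "light_resp_fold": light_fold,
        "light_resp_fold_rounded": round(light_fold, 1),
        "total_resp_fold": total_fold,
        "total_resp_fold_rounded": round(total_fold, 1),
        "n2_fixation_pct": n2_pct,
        "n2_fixation_pct_rounded": int(round(n2_pct)),
    }


_SUMMARY_COLUMNS = [
    "species", "ek_c", "etr_max_h", "etr_max_12h",
    "etr_at_growth_irradiance", "o2_day", "o2_night", "resp_day",
    "resp_night", "pmB_h", "pmB_12h", "n2_day", "n2_night", "e_demand",
    "electron_pct", "phi_max", "phi_lim", "alpha_etr", "alpha_c",
]


def write_summary_table(
    records: list[SpeciesPhysiology], path: str | Path
) -> pd.DataFrame:
    """Write ``summary_table1.csv`` with one row per species."""
    df = pd.DataFrame([r.as_dict() for r in records], columns=_SUMMARY_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_summary_table(path: str | Path) -> list[SpeciesPhysiology]:
    """Read a summary table back into physiology records (round-trip)."""
    df = pd.read_csv(path)
    return [
        SpeciesPhysiology(**{k: row[k] for k in _SUMMARY_COLUMNS})
        for _, row in df.iterrows()
    ]
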