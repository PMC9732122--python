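"""O₂ electrode rates: gross photosynthesis and 12-h diel phase budgets.

Gross O₂ evolution is reconstructed as net O₂ evolution at saturating light
plus the respiratory O₂ consumption measured in the dark immediately after
the light exposure (respiration is stored as a positive magnitude). Sparse
diel rate series are integrated per phase — light [0, 12), dark [12, 24) —
assuming piecewise-linear rates between samples, with phase edges filled by
the nearest measured value (no extrapolation beyond it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidMeasurementError, MissingPhaseError

__all__ = [
    "RateTimeseries",
    "PhaseBudget",
    "gross_o2",
    "phase_totals",
    "read_o2_table",
]

LIGHT_DARK_BOUNDARY = 12.0
CYCLE_LENGTH = 24.0


@dataclass(frozen=True)
class RateTimeseries:
    """A chlorophyll-normalized diel rate series on the hour-of-day axis.

    ``t_h`` is hours since light onset, strictly increasing within [0, 24);
    consumption series (respiration) store positive magnitudes.
    """

    t_h: tuple[float, ...]
    value: tuple[float, ...]
    label: str = "rate"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_h, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.size != v.size or t.size == 0:
            raise InvalidMeasurementError("t_h and value must match and be non-empty")
        if np.any(np.diff(t) <= 0):
            raise InvalidMeasurementError("t_h must be strictly increasing")
        if t[0] < 0 or t[-1] >= CYCLE_LENGTH:
            raise DomainError("t_h must lie within [0, 24)")
        if not np.all(np.isfinite(v)):
            raise InvalidMeasurementError("rate values must be finite")

    @classmethod
    def from_arrays(cls, t_h, value, label: str = "rate") -> "RateTimeseries":
        return cls(tuple(float(x) for x in t_h),
                   tuple(float(x) for x in value), label)


@dataclass(frozen=True)
class PhaseBudget:
    """12-h phase-integrated amounts (units inherited from the series)."""

    day_total: float
    night_total: float
    units: str = ""


def gross_o2(net_light: float, resp_dark_after_light: float) -> float:
    """Gross O₂ evolution = net evolution in light + dark respiration.

    ``resp_dark_after_light`` is the positive magnitude of O₂ consumption;
    a negative net rate (net consumption under light) is allowed.
    """
    if resp_dark_after_light < 0:
        raise DomainError(
            "respiration magnitude must be >= 0, got "
            f"{resp_dark_after_light}"
        )
    return net_light + resp_dark_after_light


def _segment_integral(t: np.ndarray, v: np.ndarray, lo: float, hi: float) -> float:
    """Exact integral of the piecewise-linear interpolant over [lo, hi].

    Outside the sampled span the series is held at its nearest endpoint
    value. Integration knots are the segment bounds plus interior samples,
    so splitting at any sample and summing is exact.
    """
    interior = t[(t > lo) & (t < hi)]
    knots = np.concatenate(([lo], interior, [hi]))
    vals = np.interp(knots, t, v)
    return float(np.trapezoid(vals, knots))


def phase_totals(
    series: RateTimeseries,
    boundary: float = LIGHT_DARK_BOUNDARY,
    method: Literal["trapezoid", "mean"] = "trapezoid",
) -> PhaseBudget:
    """Integrate a diel rate series into light- and dark-phase totals.

    ``method="mean"`` replaces the trapezoid integral by (phase mean) × 12,
    an alternative convention for sparse sampling.
    """
    t = np.asarray(series.t_h, dtype=float)
    v = np.asarray(series.value, dtype=float)
    n_day = int(np.sum(t < boundary))
    n_night = int(np.sum(t >= boundary))
    if n_day == 0 or n_night == 0:
        raise MissingPhaseError(
            f"series '{series.label}' has {n_day} light and {n_night} dark "
            "samples; both phases need coverage"
        )
    if method == "trapezoid":
        day = _segment_integral(t, v, 0.0, boundary)
        night = _segment_integral(t, v, boundary, CYCLE_LENGTH)
    elif method == "mean":
        day = float(np.mean(v[t < boundary])) * boundary
        night = float(np.mean(v[t >= boundary])) * (CYCLE_LENGTH - boundary)
    else:
        raise DomainError(f"unknown integration method {method!r}")
    return PhaseBudget(day_total=day, night_total=night, units=series.label)


def read_o2_table(path: str | Path) -> pd.DataFrame:
    """Read ``o2.csv`` (columns t_h, net_light, resp_dark)."""
    df = pd.read_csv(path)
    missing = {"t_h", "net_light", "resp_dark"} - set(df.columns)
    if missing:
        raise InvalidMeasurementError(f"{path}: missing columns {sorted(missing)}")
    return df
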