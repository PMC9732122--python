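"""Diel light schedule.

A photobioreactor driven on a sinusoidal 12:12 h light:dark cycle delivers a
half-sine irradiance profile during the photoperiod and darkness otherwise.
Time is expressed as hours since light onset, so the light phase is [0, 12)
and the dark phase [12, 24). ``1L`` means t = 1 h, ``3D`` means t = 15 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["DielLightProfile", "irradiance_at"]


@dataclass(frozen=True)
class DielLightProfile:
    """Half-sine diel irradiance schedule.

    Parameters
    ----------
    e_max : float
        Peak irradiance at the middle of the photoperiod
        (µmol photons m⁻² s⁻¹).
    photoperiod : float
        Length of the light phase in hours (default 12).
    cycle_length : float
        Length of the full diel cycle in hours (24).
    """

    e_max: float
    photoperiod: float = 12.0
    cycle_length: float = 24.0

    def __post_init__(self) -> None:
        if not self.e_max > 0:
            raise DomainError(f"e_max must be positive, got {self.e_max}")
        if not 0 < self.photoperiod < self.cycle_length:
            raise DomainError(
                f"photoperiod must lie in (0, {self.cycle_length}), "
                f"got {self.photoperiod}"
            )

    def light_integral(self) -> float:
        """Photon dose over one cycle (µmol photons m⁻² per cycle).

        Closed form of the half-sine: E_max · photoperiod · 2/π · 3600.
        """
        return self.e_max * self.photoperiod * 2.0 / math.pi * 3600.0


def irradiance_at(t: float | np.ndarray, profile: DielLightProfile):
    """Irradiance at hour-of-day ``t`` (hours since light onset).

    Returns ``E_max · sin(π t / photoperiod)`` inside the photoperiod and 0
    in the dark; continuous at both phase boundaries.

    Raises
    ------
    DomainError
        If ``t`` falls outside [0, cycle_length).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr >= profile.cycle_length)):
        raise DomainError(
            f"t must lie in [0, {profile.cycle_length}), got {t!r}"
        )
    e = profile.e_max * np.sin(np.pi * t_arr / profile.photoperiod)
    e = np.where(t_arr < profile.photoperiod, np.maximum(e, 0.0), 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(e)
    return e
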