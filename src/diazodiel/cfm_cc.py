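"""Coarse-grained cell-flux growth model and two-species competition.

Each species is reduced to a linear carbon budget: growth rate

    μᵢ(f_N) = PMaxᵢ · f_N − mᵢ        (d⁻¹)

where PMaxᵢ is the maximum photosynthesis rate, mᵢ a constant respiration
(carbon consumption) rate, and f_N ∈ [0, 1] the nutrient repletion factor
scaling realized photosynthesis (0 = fully deplete, 1 = replete
environment). Because both growth laws are linear in f_N, two species can
cross at most once: the species with the lower respiration wins in deplete
water, the one with the higher photosynthetic ceiling wins in replete
water. The crossover, when it exists inside [0, 1], is

    f_N* = (m_b − m_a) / (PMax_b − PMax_a).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "CfmParams",
    "Crossover",
    "CompetitionResult",
    "growth_rate",
    "crossover_fN",
    "run_competition",
]


@dataclass(frozen=True)
class CfmParams:
    """Per-species model parameters (both in d⁻¹)."""

    species: str
    pmax: float
    m: float

    def __post_init__(self) -> None:
        if not self.pmax > 0:
            raise DomainError(f"pmax must be positive, got {self.pmax}")
        if self.m < 0:
            raise DomainError(f"m must be >= 0, got {self.m}")


@dataclass(frozen=True)
class Crossover:
    """Where (if anywhere) two linear growth laws intersect inside [0, 1]."""

    kind: Literal["crossover", "absent", "identical"]
    fN: float | None = None


@dataclass(frozen=True)
class CompetitionResult:
    """Growth rates of two species on a uniform f_N grid and the winner map."""

    fN_grid: tuple[float, ...]
    mu_a: tuple[float, ...]
    mu_b: tuple[float, ...]
    winner: tuple[str, ...]
    crossover: Crossover

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fN": self.fN_grid,
                "mu_a": self.mu_a,
                "mu_b": self.mu_b,
                "winner": self.winner,
            }
        )

    def write(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        payload = {"kind": self.crossover.kind, "fN": self.crossover.fN}
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def growth_rate(p: CfmParams, fN: float) -> float:
    """μ = PMax·f_N − m (d⁻¹); may be negative (net carbon loss)."""
    if not 0.0 <= fN <= 1.0:
        raise DomainError(f"fN must lie in [0, 1], got {fN}")
    return p.pmax * fN - p.m


def crossover_fN(a: CfmParams, b: CfmParams) -> Crossover:
    """Intersection of the two growth laws within the admissible f_N range.

    Parallel non-identical laws never cross; identical laws are flagged
    explicitly; an intersection outside [0, 1] is reported as absent.
    """
    if a.pmax == b.pmax:
        if a.m == b.m:
            return Crossover(kind="identical")
        return Crossover(kind="absent")
    fn_star = (b.m - a.m) / (b.pmax - a.pmax)
    if 0.0 <= fn_star <= 1.0:
        return Crossover(kind="crossover", fN=float(fn_star))
    return Crossover(kind="absent")


def run_competition(a: CfmParams, b: CfmParams, n_grid: int = 101) -> CompetitionResult:
    """Evaluate both growth laws on a uniform f_N grid over [0, 1].

    The per-point winner is the species with the strictly larger μ ("tie"
    at exact equality). Linearity guarantees the winner sequence switches
    at most once along the grid.
    """
    if n_grid < 2:
        raise DomainError(f"n_grid must be >= 2, got {n_grid}")
    grid = np.linspace(0.0, 1.0, n_grid)
    mu_a = a.pmax * grid - a.m
    mu_b = b.pmax * grid - b.m
    winner = np.where(
        mu_a > mu_b, a.species, np.where(mu_b > mu_a, b.species, "tie")
    )
    return CompetitionResult(
        fN_grid=tuple(float(x) for x in grid),
        mu_a=tuple(float(x) for x in mu_a),
        mu_b=tuple(float(x) for x in mu_b),
        winner=tuple(str(w) for w in winner),
        crossover=crossover_fN(a, b),
    )
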