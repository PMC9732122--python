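"""Seeded synthetic diel photobioreactor datasets with known ground truth.

Emulates a 12:12 h sinusoidal light:dark photobioreactor run for a
unicellular diazotroph: diel OD₇₃₅ rise and fall driven by a carbon-pool
state variable, FRRf fluorescence ladders consistent with a prescribed
ETR–irradiance curve, O₂ electrode series, dark acetylene-reduction vials
accumulating ethylene at 4× the scheduled N₂-fixation rate, and a ¹⁴C
photosynthetron ladder consistent with a prescribed carbon P–E curve.

Every instrument readout carries multiplicative Gaussian noise with a
configurable coefficient of variation (truncated at zero); one integer seed
drives an independent named RNG stream per instrument, so a dataset is
reproduced bit-for-bit from its seed. Two presets mirror the study
organisms: an oligotrophic open-ocean type ("Crocosphaera-like": large diel
OD amplitude, late nocturnal N₂-fixation window, low respiration) and a
coastal type ("Cyanothece-like": damped OD amplitude, fixation from dusk,
high respiration).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon_uptake import DEFAULT_DIC, DEFAULT_DISCRIMINATION
from .errors import ConfigError, DomainError, InfeasibleTargetError
from .frr_etr import EtrContext, FrrfYieldSet, PECurveFit, etr_from_yields
from .gas_exchange import RateTimeseries, phase_totals
from .light import DielLightProfile, irradiance_at
from .n2_fixation import R_L_ATM

__all__ = [
    "DielLightProfile",
    "irradiance_at",
    "SyntheticTruth",
    "SyntheticDielDataset",
    "yields_for_etr",
    "generate_diel_dataset",
    "crocosphaera_like",
    "cyanothece_like",
]

#: Photosynthetic quotient (mol O₂ per mol C) used only by the OD carbon pool.
PQ = 1.4

#: Hours (since light onset) at which FRRf ladders are taken.
FRRF_SAMPLE_HOURS = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0)
#: Irradiance steps of one FRRf P–E ladder (µmol photons m⁻² s⁻¹).
FRRF_LADDER = tuple(np.linspace(0.0, 1500.0, 11))
#: Irradiance levels of the ¹⁴C photosynthetron ladder.
C14_LADDER = (0.0, 20.0, 45.0, 85.0, 150.0, 250.0, 400.0, 600.0,
              850.0, 1100.0, 1300.0, 1528.0)

_NOISE_STREAMS = {"od": 1, "frrf": 2, "o2": 3, "ara": 4, "c14": 5}


def yields_for_etr(
    target_etr: float,
    E: float,
    fvfm: float,
    chl: float,
    ka: float = 11800.0,
) -> FrrfYieldSet:
    """Fluorescence yields whose absorption-method ETR equals ``target_etr``.

    F₀ is normalized to 1 and F_m fixed by the dark-regulated quantum yield
    F_v/F_m; the light-phase yields are chosen with F_m′ = F_m (no
    quenching) and F′ set so the photochemical yield reproduces the target.
    Exact inverse of :func:`diazodiel.frr_etr.etr_from_yields` under the
    as-printed 1/3600 convention.
    """
    if not E > 0:
        raise DomainError(f"E must be positive, got {E}")
    if not 0 < fvfm < 1:
        raise DomainError(f"fvfm must lie in (0, 1), got {fvfm}")
    if target_etr < 0:
        raise InfeasibleTargetError(f"target ETR must be >= 0, got {target_etr}")
    f0 = 1.0
    fm = f0 / (1.0 - fvfm)
    # (Fm·F0)/(Fm−F0) = 1/fvfm with F0 = 1
    q = target_etr * 3600.0 * chl * fvfm / (ka * E)
    if q >= 1.0:
        raise InfeasibleTargetError(
            f"target ETR {target_etr} at E={E} implies photochemical yield "
            f"{q:.3f} >= 1"
        )
    fmp = fm
    fp = fmp * (1.0 - q)
    return FrrfYieldSet(F0=f0, Fm=fm, Fp=fp, Fmp=fmp, E=E)


@dataclass
class SyntheticTruth:
    """Ground-truth parameter bundle for one synthetic species run.

    ``n2fix_schedule`` maps hour-of-day (0 = light onset) to the N₂-fixation
    rate in nmol N₂ (µg Chl a)⁻¹ h⁻¹ and must be zero outside the dark
    phase. O₂ rates are hourly Chl-normalized rates
    (µmol O₂ (µg Chl a)⁻¹ h⁻¹); respiration is a positive magnitude.
    """

    species: str
    pe_params_etr: PECurveFit
    pe_params_c: PECurveFit
    resp_light: float
    resp_dark: float
    gross_o2_day: float
    gross_o2_night: float
    n2fix_schedule: dict[float, float]
    fvfm: float
    chl: float
    od_params: dict[str, float]
    noise_cv: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not 0 < self.fvfm < 1:
            raise DomainError(f"fvfm must lie in (0, 1), got {self.fvfm}")
        if not self.chl > 0:
            raise DomainError(f"chl must be positive, got {self.chl}")
        for name in ("resp_light", "resp_dark", "gross_o2_day", "gross_o2_night"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for hour, rate in self.n2fix_schedule.items():
            if rate < 0:
                raise DomainError(f"N2 rate at {hour} h must be >= 0")
            if rate > 0 and not 12.0 <= hour < 24.0:
                raise DomainError(
                    f"nonzero N2 fixation at {hour} h lies outside the dark phase"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["pe_params_etr"] = asdict(self.pe_params_etr)
        d["pe_params_c"] = asdict(self.pe_params_c)
        d["n2fix_schedule"] = {str(k): v for k, v in self.n2fix_schedule.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["pe_params_etr"] = PECurveFit(**d["pe_params_etr"])
        d["pe_params_c"] = PECurveFit(**d["pe_params_c"])
        d["n2fix_schedule"] = {
            float(k): v for k, v in d["n2fix_schedule"].items()
        }
        return cls(**d)


@dataclass
class SyntheticDielDataset:
    """All generated series for one species, plus the emitting truth.

    Frames use the hour-of-day axis (0 = light onset) and parse through the
    pipeline's CSV readers without special-casing.
    """

    light: pd.DataFrame
    od: pd.DataFrame
    frrf_tables: dict[float, pd.DataFrame]
    o2: pd.DataFrame
    ethylene_vials: pd.DataFrame
    c14_counts: pd.DataFrame
    truth: SyntheticTruth
    profile: DielLightProfile

    def write(self, out_dir: str | Path) -> Path:
        """Write the CSV dialects the pipeline reads, plus ``truth.json``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.light.to_csv(out / "light.csv", index=False)
        self.od.to_csv(out / "od.csv", index=False)
        for t, table in self.frrf_tables.items():
            table.to_csv(out / f"frrf_{t:g}.csv", index=False)
        self.o2.to_csv(out / "o2.csv", index=False)
        self.ethylene_vials.to_csv(out / "ara.csv", index=False)
        self.c14_counts.to_csv(out / "c14.csv", index=False)
        (out / "truth.json").write_text(self.truth.to_json() + "\n")
        return out


def _noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative Gaussian noise with coefficient of variation ``cv``,
    truncated at zero."""
    values = np.asarray(values, dtype=float)
    if cv == 0:
        return values.copy()
    factors = np.maximum(0.0, 1.0 + cv * rng.standard_normal(values.shape))
    return values * factors


def _carbon_pool(
    truth: SyntheticTruth, profile: DielLightProfile, t_grid: np.ndarray
) -> np.ndarray:
    """Cumulative carbon-pool excursion X(t) driving the OD model.

    dX/dt = P_C(E(t)) − R(t)/PQ, in µmol C (µg Chl)⁻¹; X(0) = 0.
    """
    e = irradiance_at(t_grid, profile)
    photo = truth.pe_params_c(e)
    resp_c = np.where(
        t_grid < profile.photoperiod, truth.resp_light, truth.resp_dark
    ) / PQ
    dx = photo - resp_c
    x = np.concatenate(
        ([0.0], np.cumsum((dx[1:] + dx[:-1]) / 2.0 * np.diff(t_grid)))
    )
    return x


def _solve_od_gain(
    truth: SyntheticTruth, profile: DielLightProfile
) -> tuple[float, np.ndarray, np.ndarray]:
    """Calibrate the OD gain so the 1L-normalized series peaks at the
    preset fold amplitude."""
    t_grid = np.arange(0.0, profile.cycle_length, 0.01)
    x = _carbon_pool(truth, profile, t_grid)
    peak_fold = truth.od_params["peak_fold"]
    x1 = float(np.interp(1.0, t_grid, x))
    xmax = float(x.max())
    denom = xmax - peak_fold * x1
    if denom <= 0:
        raise ConfigError(
            f"cannot reach a {peak_fold}-fold OD amplitude with this physiology"
        )
    gamma = (peak_fold - 1.0) / denom
    return gamma, t_grid, x


def generate_diel_dataset(
    truth: SyntheticTruth,
    profile: DielLightProfile,
    dic: float = DEFAULT_DIC,
    discrimination: float = DEFAULT_DISCRIMINATION,
    c14_t_inc: float = 0.5,
    c14_dpm_total: float = 1e6,
    c14_dpm_blank: float = 200.0,
    ara_headspace_ml: float = 10.0,
    ara_sample_ml: float = 5.0,
    ara_t0_ppm: float = 0.1,
    temperature_c: float = 28.0,
    pressure_atm: float = 1.0,
) -> SyntheticDielDataset:
    """Generate one full synthetic diel dataset from a truth bundle.

    The same seed always produces the same dataset; at ``noise_cv = 0`` the
    pipeline recovers the generating P–E parameters and N₂ schedule
    essentially exactly (all inversions here are closed-form).
    """
    rngs = {
        name: np.random.default_rng([int(truth.seed), idx])
        for name, idx in _NOISE_STREAMS.items()
    }
    cv = truth.noise_cv

    # programmed light schedule (noise-free by construction)
    t_light = np.round(np.arange(0.0, profile.cycle_length, 0.1), 10)
    light = pd.DataFrame(
        {"t_h": t_light, "E": irradiance_at(t_light, profile)}
    )

    # OD735 from the carbon-pool state variable
    gamma, t_grid, x = _solve_od_gain(truth, profile)
    od0 = truth.od_params.get("od0", 0.2)
    truth.od_params["gamma"] = gamma
    od_true = od0 * (1.0 + gamma * np.interp(t_light, t_grid, x))
    od = pd.DataFrame(
        {"t_h": t_light, "od735": _noise(rngs["od"], od_true, cv)}
    )

    # FRRf ladders: invert the ETR equation at every ladder step. Noise is
    # applied to the fitted photophysical quantities the instrument reports
    # (F0, Fv/Fm and the photochemical yield), not to F' and Fm'
    # independently: the difference of two independently noised levels
    # would have unbounded relative error at the small realistic yields.
    rng_frrf = rngs["frrf"]
    frrf_tables: dict[float, pd.DataFrame] = {}
    for t in FRRF_SAMPLE_HOURS:
        rows = []
        for e_step in FRRF_LADDER:
            if e_step == 0.0:
                # dark step: F' relaxes to F0, Fm' to Fm
                q_true = truth.fvfm
            else:
                clean = yields_for_etr(
                    truth.pe_params_etr(e_step), e_step, truth.fvfm, truth.chl
                )
                q_true = (clean.Fmp - clean.Fp) / clean.Fmp
            f0 = float(_noise(rng_frrf, np.array(1.0), cv))
            fvfm = float(
                np.clip(_noise(rng_frrf, np.array(truth.fvfm), cv), 0.05, 0.95)
            )
            fm = f0 / (1.0 - fvfm)
            fmp = max(float(_noise(rng_frrf, np.array(fm), cv)), 1e-6)
            q = float(np.clip(_noise(rng_frrf, np.array(q_true), cv), 0.0, 0.999))
            rows.append(
                {"E": e_step, "F0": f0, "Fm": fm,
                 "Fp": fmp * (1.0 - q), "Fmp": fmp}
            )
        frrf_tables[t] = pd.DataFrame(rows)

    # O2 electrode series: odd hours, 6 light + 6 dark samples
    t_o2 = np.arange(1.0, 24.0, 2.0)
    in_light = t_o2 < profile.photoperiod
    gross = np.where(in_light, truth.gross_o2_day, truth.gross_o2_night)
    resp = np.where(in_light, truth.resp_light, truth.resp_dark)
    o2 = pd.DataFrame(
        {
            "t_h": t_o2,
            "net_light": _noise(rngs["o2"], gross - resp, cv),
            "resp_dark": _noise(rngs["o2"], resp, cv),
        }
    )

    # ARA vials: one dark 1-h incubation per scheduled hour; ethylene
    # accumulates linearly at 4x the scheduled N2 rate
    t_kelvin = temperature_c + 273.15
    chl_per_ml = truth.chl / 1000.0  # mg m^-3 == µg L^-1 -> µg mL^-1
    vial_rows = []
    for hour in sorted(truth.n2fix_schedule):
        n2 = truth.n2fix_schedule[hour]
        eth_nmol_h = 4.0 * n2 * chl_per_ml * ara_sample_ml
        mol = eth_nmol_h * 1e-9 * 1.0  # 1 h incubation
        dppm = mol * R_L_ATM * t_kelvin / (
            pressure_atm * ara_headspace_ml / 1000.0
        ) * 1e6
        vial_rows.append(
            {
                "vial": hour,
                "t0_ppm": ara_t0_ppm,
                "t1_ppm": ara_t0_ppm + dppm,
                "dt_h": 1.0,
                "headspace_ml": ara_headspace_ml,
                "sample_ml": ara_sample_ml,
            }
        )
    vials = pd.DataFrame(vial_rows)
    vials["t1_ppm"] = ara_t0_ppm + _noise(
        rngs["ara"], (vials["t1_ppm"] - ara_t0_ppm).to_numpy(), cv
    )

    # 14C photosynthetron ladder: invert the tracer equation
    c14_rows = []
    for e_step in C14_LADDER:
        rate = truth.pe_params_c(e_step)
        net_dpm = rate * c14_t_inc * truth.chl * c14_dpm_total / (
            dic * discrimination
        )
        c14_rows.append(
            {
                "E": e_step,
                "dpm": c14_dpm_blank + net_dpm,
                "dpm_blank": c14_dpm_blank,
                "dpm_total": c14_dpm_total,
            }
        )
    c14 = pd.DataFrame(c14_rows)
    c14["dpm"] = c14["dpm_blank"] + _noise(
        rngs["c14"], (c14["dpm"] - c14["dpm_blank"]).to_numpy(), cv
    )

    return SyntheticDielDataset(
        light=light,
        od=od,
        frrf_tables=frrf_tables,
        o2=o2,
        ethylene_vials=vials,
        c14_counts=c14,
        truth=truth,
        profile=profile,
    )


def _scaled_schedule(
    shape: dict[float, float], night_total_nmol: float
) -> dict[float, float]:
    """Scale an hourly dark-phase shape so its trapezoidal night integral
    (with nearest-sample edge extension) equals ``night_total_nmol``."""
    hours = [float(h) for h in range(24)]
    values = [shape.get(h, 0.0) for h in hours]
    series = RateTimeseries.from_arrays(hours, values, label="n2fix")
    budget = phase_totals(series)
    scale = night_total_nmol / budget.night_total
    return {h: shape.get(h, 0.0) * scale for h in hours}


def crocosphaera_like(noise_cv: float = 0.05, seed: int = 0) -> SyntheticTruth:
    """Open-ocean (oligotrophic) preset.

    High-light-adapted carbon P–E curve (E_K^C = 331 µmol quanta m⁻² s⁻¹,
    P_m^B = 0.237 µmol C (µg Chl)⁻¹ h⁻¹), ETR_max 1.260 µmol e⁻
    (µg Chl)⁻¹ h⁻¹ with α^ETR/α^C = 3.7, low light-phase respiration,
    strong diel OD amplitude (2.3-fold at peak) and a late nocturnal
    N₂-fixation window peaking near 10 h into the dark (night total
    77.1 nmol N₂ (µg Chl)⁻¹).
    """
    alpha_c = 0.237 / 331.0
    n2_shape = {17.0: 0.2, 18.0: 1.5, 19.0: 5.2, 20.0: 13.5, 21.0: 25.4,
                22.0: 31.7, 23.0: 0.0}
    return SyntheticTruth(
        species="crocosphaera",
        pe_params_etr=PECurveFit.from_photo_params(
            alpha=3.7 * alpha_c, pmax=1.260, eopt=1200.0
        ),
        pe_params_c=PECurveFit.from_photo_params(
            alpha=alpha_c, pmax=0.237, eopt=1100.0
        ),
        resp_light=0.51 / 12.0,
        resp_dark=1.19 / 12.0,
        gross_o2_day=2.04 / 12.0,
        gross_o2_night=1.14 / 12.0,
        n2fix_schedule=_scaled_schedule(n2_shape, 77.1),
        fvfm=0.45,
        chl=100.0,
        od_params={"od0": 0.2, "peak_fold": 2.3},
        noise_cv=noise_cv,
        seed=seed,
    )


def cyanothece_like(noise_cv: float = 0.05, seed: int = 0) -> SyntheticTruth:
    """Coastal (nutrient-rich) preset.

    Low-light-adapted carbon P–E curve (E_K^C = 88 µmol quanta m⁻² s⁻¹,
    P_m^B = 0.175 µmol C (µg Chl)⁻¹ h⁻¹), ETR_max 2.290 µmol e⁻
    (µg Chl)⁻¹ h⁻¹, high respiration in both phases, damped diel OD
    amplitude (1.6-fold) and N₂ fixation starting at dusk, peaking 6 h into
    the dark (night total 93.7 nmol N₂ (µg Chl)⁻¹).
    """
    alpha_c = 0.175 / 88.0
    n2_shape = {12.0: 0.5, 13.0: 1.0, 14.0: 1.5, 15.0: 2.5, 16.0: 6.0,
                17.0: 21.0, 18.0: 43.0, 19.0: 14.0, 20.0: 3.5, 21.0: 1.0,
                22.0: 0.3, 23.0: 0.0}
    return SyntheticTruth(
        species="cyanothece",
        pe_params_etr=PECurveFit.from_photo_params(
            alpha=3.7 * alpha_c, pmax=2.290, eopt=900.0
        ),
        pe_params_c=PECurveFit.from_photo_params(
            alpha=alpha_c, pmax=0.175, eopt=600.0
        ),
        resp_light=1.10 / 12.0,
        resp_dark=0.92 / 12.0,
        gross_o2_day=3.09 / 12.0,
        gross_o2_night=2.22 / 12.0,
        n2fix_schedule=_scaled_schedule(n2_shape, 93.7),
        fvfm=0.5,
        chl=100.0,
        od_params={"od0": 0.25, "peak_fold": 1.6},
        noise_cv=noise_cv,
        seed=seed,
    )
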