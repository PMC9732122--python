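# Methods

This note documents the models implemented in `diazodiel`, the parameter
defaults and their units, the numerical choices, and the design decisions
taken where the underlying measurement conventions are genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Time convention

All diel series use hours since light onset: light phase `[0, 12)`, dark
phase `[12, 24)`; "3L" means t = 3 h, "6D" means t = 18 h. The
photobioreactor light schedule is a half-sine,
E(t) = E_max·sin(πt/photoperiod) inside the photoperiod and 0 outside,
continuous at both boundaries (the boundary itself belongs to the dark
phase). The photon dose over one cycle has the closed form
E_max · photoperiod · 2/π · 3600 µmol photons m⁻², used as an analytic
check on the numerical integrators.

## Electron transport from FRR fluorometry

Absolute Chl-normalized ETR follows the absorption method:
ETR = (F_m·F₀)/(F_m−F₀) · (F_m′−F′)/F_m′ · E · K_A/[Chl a] · (1/3600),
in µmol e⁻ (µg Chl a)⁻¹ h⁻¹, with K_A = 11800 m⁻¹ (instrument calibration
factor, configurable) and [Chl a] in mg m⁻³.

**Unit audit.** The formula is implemented exactly as published, dividing
by 3600. A dimensional reading of the factor as a seconds→hours conversion
would multiply instead; since the published arithmetic is the reference,
"divide" is the default and `EtrContext.time_factor = "multiply"` flips it
for users who prefer the dimensional reading. All shipped defaults,
synthetic inversions and tests use the as-published convention
consistently, so the choice cancels everywhere inside the package.

Degenerate inputs are rejected rather than propagated: F_m = F₀ (no
variable fluorescence) and F′ > F_m′ are measurement errors, not data.

## P–E curve model and fitting

Both the ETR and the ¹⁴C stage share one fitter for the Eilers–Peeters
rational response P(E) = E/(aE² + bE + c), chosen because it yields a
maximum (P_max or ETR_max), an initial slope α and a photoinhibition
optimum E_opt from one three-parameter form:
α = 1/c, P_max = 1/(b + 2√(ac)), E_opt = √(c/a), E_K = P_max/α (the E_K
identity is exact by construction in the fit record).

Numerical choices:

* The least-squares problem is solved in log(α, P_max, E_opt) space. In
  that parametrization the denominator is positive for every E ≥ 0 and the
  response always has a finite positive maximum, so no penalty terms or
  post-hoc validity checks are needed; coefficient-space box bounds cannot
  express the constraint b > −2√(ac).
* E_opt is capped at 10× the largest sampled irradiance. Beyond that the
  (P_max, E_opt) pair is unidentifiable — noisy, barely-photoinhibited
  ladders otherwise trade an absurd P_max against an astronomical E_opt
  while fitting the sampled range perfectly. A fit at the cap simply means
  "no photoinhibition detectable"; `from_photo_params` with E_opt = ∞
  (a = 0) is the exact limiting form.
* Initialisation from the data shape: α₀ from the slope of the two
  lowest positive irradiances, P_max₀ from the maximum response, E_opt₀ at
  twice the location of that maximum (capped below the bound). Relative
  tolerance 1e−8 (applied with margin as `xtol`/`ftol`), at most 5000
  function evaluations; non-convergence raises a fit-failure error
  carrying solver diagnostics.
* Fits require ≥4 distinct irradiance levels with non-negative, not
  all-zero responses, and are invariant to point ordering. On noise-free
  model-generated ladders the coefficients are recovered to ~1e−15
  relative (asserted at 1e−6 in tests).

**ETR_max conventions.** The summary carries ETR_max both as the
instantaneous maximum of the fitted curve (per hour) and as ×12 (per
12-h phase), plus the diel integral of the fitted curve along the actual
growth light profile ("ETR at growth irradiance"). Published 12-h tables
mix these conventions and no single one reproduces all printed values, so
all are emitted and none silently preferred.

Diel integrals use the composite trapezoid along the half-sine schedule
with step dt ≤ 0.25 h (default 0.05 h); a purely light-limited response
integrates to α·E_max·24/π over the photoperiod, an exact check used in
the tests. The dark-phase integral of any light-driven response is 0
because P(0) = 0.

## ¹⁴C carbon incorporation

rate = max(0, dpm − dpm_blank)/dpm_total · DIC · discrimination / t_inc /
Chl, in µmol C (µg Chl a)⁻¹ h⁻¹. Defaults: DIC = 2050 µmol L⁻¹ (typical
seawater medium), isotope discrimination 1.05, incubation 0.5 h — all
configurable, because the source protocols cite these externally rather
than printing them. Killed-control blanks exceeding the sample clamp the
rate to zero with a warning (counting noise at zero uptake, not an
error). The rate is invariant under joint rescaling of all three dpm
figures (counting-efficiency invariance).

## O₂ gas exchange

Gross O₂ evolution = net evolution at saturating light + the respiratory
consumption measured in the dark immediately after illumination
(respiration series store positive magnitudes; signs enter only in budget
arithmetic). Phase budgets integrate the piecewise-linear interpolant of
the diel rate series over [0, 12] and [12, 24]; where the samples do not
reach a phase edge the nearest measured value is extended flat (no
extrapolation). This makes the integral exactly additive under splitting
at any interior point. Whether published 12-h totals were trapezoid
integrals or phase-mean × 12 is not documented; trapezoid is the default
and `method="mean"` is available.

## Acetylene reduction and the electron budget

Headspace-only accounting: Δppm ethylene → moles via n = x·P·V/(R·T)
(R = 0.08206 L·atm mol⁻¹ K⁻¹, vial temperature 28 °C and 1 atm by
default), per incubation hour and per total µg Chl in the vial. Ethylene
dissolved in the 5 mL liquid phase is neglected; this is exact for the
synthetic data and a small underestimate (order of the Bunsen coefficient
× liquid/headspace ratio) for real vials. N₂ fixation = ethylene rate / 4
(theoretical acetylene:N₂ electron-pair ratio); electron demand =
8 e⁻ × N₂ fixed (6 for the reduction plus the obligatory H₂ evolution);
the percentage of daytime electrons devoted to fixation divides that
demand by the light-phase ETR integral.

## Physiology summary and reporting

OD₇₃₅ series are normalized to their (interpolated) value 1 h after light
onset, the earliest stable reading of each cycle; the analysis smooths the
high-frequency reactor trace with a centred 0.5 h rolling mean before
anchor and peak extraction, so the reported peak fold is not an
extreme-value statistic of readout noise. Φ_max = ETR_max/P_m^B is
computed from the hourly means; note that ratio-of-means and
mean-of-per-timepoint-ratios differ for diel data, which is why published
Φ_max values can disagree with the ratio of the published mean rates.
Reporting rounds ratios to 1 decimal, percentages to integers and
electron amounts to 2 decimals, always retaining the raw values alongside.

## Growth model (CFM-CC)

μᵢ(f_N) = PMaxᵢ·f_N − mᵢ (d⁻¹) with the nutrient repletion factor
f_N ∈ [0, 1]. Growth is linear in f_N, so the winner map over any grid has
at most one transition and the crossover has the closed form
f_N* = (m_b−m_a)/(PMax_b−PMax_a), reported only inside [0, 1]; parallel
laws are "absent", identical laws "identical", ties are labelled
explicitly. Absolute PMax/m values for the study strains are not publicly
tabulated; by default each species' measured day-phase gross O₂ maps to
PMax and its total daily respiration to m through a single
proportionality constant κ (default 1 d⁻¹ per µmol O₂ (µg Chl)⁻¹ 12 h⁻¹).
κ rescales both axes of the competition diagram but cannot change the
ordering or the crossover location, which are the scientifically
meaningful outputs. Explicit per-species (pmax, m) pairs in the config
override the mapping.

## Synthetic data generator

The generator emulates one diel photobioreactor cycle per species with
fully known ground truth, inverting the same equations the analysis
applies:

* **Light** — half-sine 12:12 profile, E_max 400 (open-ocean preset) or
  130 (coastal preset) µmol photons m⁻² s⁻¹, the strains' respective
  growth optima.
* **FRRf ladders** at 1, 3, 5, 7, 9, 11 h into the light phase, 11 steps
  from 0 to 1500 µmol photons m⁻² s⁻¹; yields are the closed-form inverse
  of the ETR equation at the true ETR curve value (F₀ normalized to 1,
  F_m fixed by F_v/F_m, F_m′ = F_m, F′ from the required photochemical
  yield).
* **OD₇₃₅** — proportional to a carbon-pool state variable integrating
  the true carbon P–E curve along the light profile minus respiration
  (photosynthetic quotient 1.4 for the O₂→C conversion); the gain is
  calibrated so the 1L-normalized series peaks at the preset fold
  (2.3 open-ocean, 1.6 coastal).
* **O₂ series** — phase-constant gross-capacity and respiration rates
  anchored to the published 12-h phase budgets, sampled at the 12 odd
  hours.
* **ARA vials** — one 1-h dark incubation per hour; ethylene accumulates
  linearly at 4× the scheduled N₂ rate through the exact ideal-gas
  inverse. The hourly fixation schedules are shaped like the observed
  nocturnal windows (late, peaked near 10 h into darkness for the
  open-ocean preset; from dusk, peaked near 6 h for the coastal preset)
  and scaled so the trapezoid night total equals the published daily
  fixation (77.1 and 93.7 nmol N₂ (µg Chl)⁻¹).
* **¹⁴C ladder** — 12 irradiance levels to 1528 µmol photons m⁻² s⁻¹,
  counts from the exact tracer inverse over a blank of 200 dpm.

**Noise model.** Multiplicative Gaussian noise with a configurable CV
(default 0.05), truncated at zero, one named RNG stream per instrument,
all derived from one integer seed; the same seed reproduces every CSV
byte-for-byte. For the FRRf tables the CV applies to the quantities the
instrument actually reports — F₀, F_v/F_m and the photochemical yield —
rather than to F′ and F_m′ independently: at realistic yields of a few
percent, the difference of two independently perturbed fluorescence
levels has unbounded relative error and can violate the F_m′ ≥ F′
ordering, which no curve-fitting instrument output does.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PSII photophysics (no σ_PSII, connectivity or
NPQ; F_m′ = F_m by construction), diel modulation of photosynthetic
capacity (the truth P–E parameters are time-invariant, while real
ladders drift over the day), O₂-capacity dynamics within a phase,
ethylene dissolution, cell division and size structure, and any
systematic (non-Gaussian, correlated) instrument error.

**Preset consistency limits.** The presets are anchored to the published
phase budgets, but the published quantities are themselves mutually
over-determined and not exactly consistent; where they conflict the
presets prioritize E_K^C, the hourly ETR_max/P_m^B means, Φ_lim = 3.7,
the phase O₂/respiration budgets and the daily N₂ totals. The "ETR at
growth irradiance" that follows from these choices differs from the
published 12-h value for the coastal strain (the printed α-related
quantities cannot all hold simultaneously), so the synthetic electron
percentage for that strain lands near 11 % rather than 9.3 %; the
desk-scale computation from the published inputs themselves reproduces
9.3 %.

## Problem sizes and runtime

The shipped configuration analyses 6 FRRf ladders × 11 steps, 12 ¹⁴C
levels, 12 O₂ samples, 24 ARA vials and a 240-point OD trace per species,
with a 101-point competition grid; the full two-species pipeline runs in
~1 s and the complete test suite (139 tests, including 1000-pair
crossover property checks) in a few seconds on one CPU.

## Known limitations

* The Eilers–Peeters form cannot represent responses with a plateau and
  no decline exactly; the E_opt cap makes such fits well-behaved but
  reported E_opt values at the cap should be read as "none detected".
* Phase budgets from 6 samples per phase carry O(h²) trapezoid error with
  h = 2 h spacing; the error is quantified by the step-refinement tests
  but not corrected.
* Φ_max from ratio-of-means is reported; per-timepoint Φ statistics would
  require replicate-level inputs the summary format does not carry.
* The growth model has no nutrient drawdown, mortality or grazing terms;
  it ranks steady growth rates only.
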