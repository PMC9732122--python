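# diazodiel

Diel photophysiology and electron budgets of unicellular marine
diazotrophs, with a coarse-grained growth/competition model.

Unicellular nitrogen-fixing cyanobacteria such as *Crocosphaera watsonii*
(open-ocean UCYN-B) and *Cyanothece* sp. ATCC51142 (coastal UCYN-C)
photosynthesize by day and fix N₂ by night, because nitrogenase is
destroyed by the O₂ that photosynthesis evolves. Quantifying how each
species budgets its photosynthetic electrons and fixed carbon across the
12:12 h light:dark cycle — and what that implies for which one wins in
nutrient-rich versus nutrient-poor water — requires stitching together
several instrument streams. `diazodiel` turns those raw streams into a
single, reproducible physiology summary:

* **FRR fluorometry → electron transport.** Absolute, chlorophyll-normalized
  PSII electron transport rates from fluorescence yields via the
  absorption method,

  `ETR = (F_m·F₀)/(F_m−F₀) · (F_m′−F′)/F_m′ · E · K_A/[Chl a] · (1/3600)`,

  with K_A = 11800 m⁻¹, followed by an Eilers–Peeters fit
  `P(E) = E/(aE² + bE + c)` giving α = 1/c, P_max = 1/(b+2√(ac)),
  E_opt = √(c/a) and E_K = P_max/α.
* **¹⁴C tracer uptake → carbon fixation.** Standard single-endpoint tracer
  calculus (net dpm fraction × DIC × isotope discrimination, per hour and
  per µg Chl *a*), fitted with the same P–E model to give the assimilation
  number P_m^B, α^C and E_K^C.
* **O₂ electrode → gross photosynthesis and respiration.** Gross evolution
  = net evolution in light + dark respiration measured immediately after
  illumination; sparse diel series are trapezoid-integrated into 12-h
  light/dark phase budgets.
* **Acetylene reduction → N₂ fixation.** Headspace ethylene converted with
  the ideal-gas law, the theoretical 4:1 C₂H₄:N₂ ratio, and 8 e⁻ per N₂
  to link nocturnal fixation back to the daytime electron supply.
* **Electron economy.** Φ_max = ETR_max/P_m^B and Φ_lim = α^ETR/α^C
  (electrons per carbon at saturating and limiting light), respiration as
  a fraction of gross photosynthesis, and cross-species fold ratios.
* **Competition (CFM-CC).** A linear cell-flux growth law per species,
  μᵢ = PMaxᵢ·f_N − mᵢ, on the nutrient repletion factor f_N ∈ [0, 1];
  two species can cross at most once, at
  f_N* = (m_b−m_a)/(PMax_b−PMax_a).

A fully seeded synthetic-data module emulates the photobioreactor
experiments (sinusoidal 12:12 light, diel OD₇₃₅ rise/fall driven by a
carbon-pool state variable, FRRf ladders, nocturnal fixation windows,
configurable measurement noise) with known ground truth, so every stage is
testable by exact parameter recovery.

## Worked example

The published phase-integrated rates of the two strains ship in
`diazodiel.datasets`; the electron budget follows in a few lines:

```python
from diazodiel.datasets import CROCOSPHAERA_MEASURED as cro, CYANOTHECE_MEASURED as cya
from diazodiel.n2_fixation import ConversionConstants, electron_demand, electron_fraction
from diazodiel.budgets import phi_max, respiration_fraction
from diazodiel.cfm_cc import CfmParams, crossover_fN

k = ConversionConstants()          # 4:1 acetylene:N2, 8 e- per N2
for name, rec in (("Crocosphaera", cro), ("Cyanothece", cya)):
    demand = electron_demand(rec["n2_daily_umol"], k)
    pct = electron_fraction(demand, rec["etr_at_growth_12h"])
    print(f"{name}: e- demand {demand:.2f} umol e- (ug Chl)-1 d-1, "
          f"{pct:.1f} % of daytime electron transport, "
          f"phi_max {phi_max(rec['etr_max_h'], rec['pmB_h']):.1f} e- C-1, "
          f"light-phase respiration {respiration_fraction(rec['resp_day'], rec['o2_day']):.0f} % of gross O2")

a = CfmParams("Crocosphaera", cro["o2_day"], cro["resp_day"] + cro["resp_night"])
b = CfmParams("Cyanothece",  cya["o2_day"], cya["resp_day"] + cya["resp_night"])
print("growth-law crossover at f_N =", round(crossover_fN(a, b).fN, 3))
```

prints

```
Crocosphaera: e- demand 0.62 umol e- (ug Chl)-1 d-1, 9.1 % of daytime electron transport, phi_max 5.3 e- C-1, light-phase respiration 25 % of gross O2
Cyanothece: e- demand 0.75 umol e- (ug Chl)-1 d-1, 9.3 % of daytime electron transport, phi_max 13.1 e- C-1, light-phase respiration 36 % of gross O2
growth-law crossover at f_N = 0.305
```

Reading: fixing the nightly N₂ costs each strain ~9 % of the electrons it
transports by day. *Crocosphaera* couples electrons to carbon ~2.5× more
tightly at saturating light (Φ_max 5.3 vs 13.1 e⁻ C⁻¹) and respires away a
smaller share of its gross photosynthesis (25 % vs 36 %). Mapping those
carbon budgets onto the growth law, *Crocosphaera* outgrows *Cyanothece*
below f_N ≈ 0.30 (oligotrophic open ocean) and loses above it
(nutrient-rich coastal water) — the niche separation follows from the
photosynthesis/respiration balance alone.

## Full pipeline

```sh
diazodiel all --seed 1 --out out/          # simulate + analyze + compete
```

runs the shipped two-species synthetic configuration: writes one dataset
per species (`light.csv`, `od.csv`, `frrf_<t>.csv`, `o2.csv`, `ara.csv`,
`c14.csv`, `truth.json`), analyses them (`pe_fit.csv`,
`phase_budgets.csv`, `n2fix_rates.csv` per species) and assembles
`summary_table1.csv`, `comparison.json`, `competition.csv`,
`crossover.json` and a provenance `run_log.json`. Identical config + seed
reproduces every file byte-for-byte. `diazodiel analyze --config cfg.yaml`
accepts the same CSV dialects for real instrument exports
(`mode: csv`).

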