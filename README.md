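# chlorolake

Species-level dynamics of a small, shallow urban lake under pulsed chlorine
dosing.

Urban lakes suffer recurrent eutrophication, and low-dose calcium
hypochlorite application is one practical countermeasure: hypochlorous acid
suppresses algae, but it also hits zooplankton and other biota, so managers
need a quantitative picture of the whole food web's response before dosing.
`chlorolake` implements a daily-step compartment model for exactly that
setting: 14 species across five guilds — a submerged macrophyte
(*Vallisneria natans*), four phytoplankton, three periphyton, three
zooplankton and three benthos species — coupled to a detritus pool and to
total phosphorus (TP) in water and sediment, with chlorine as the single
management intervention.

The package is aimed at researchers and lake managers who want to explore
dosing schedules, species sensitivities and phosphorus pulses in a
transparent, scriptable model, and at modellers who want a tested reference
implementation of this family of Stella-style difference models.

## Model

Per species *i* with biomass density `Biom(i)` (guild-scoped units), the
daily balances are

```
producers:  dBiom/dt = Growth − Mortality − Respiration        (− Settling − Grazing for phytoplankton)
consumers:  dBiom/dt = Grazing − Mortality − Respiration
```

with the process rates

```
Growth     = Maxg · Biom · pw/(pw+Ip) · Tk^(T−20) · sr/(sr+Ik) · exp(−Sk·Biom) [· exp(−Smk·Biomsvm)]
Mortality  = Maxm · Biom · Tk^(T−20) · exp(Kcc · Cc · M)        M = 1000 (plankton), 100 (benthos)
Respiration= Maxr · Biom · Tk^(T−20)
Grazing    = Biomzoo · Ae · Ib · Tk^(T−20) · (1−Rf) · (Biomphy−0.5)/(Biomphy+Kpz) · exp(−Sk·Biomzoo)
             (zooplankton on phytoplankton; floored at zero below the 0.5 prey refuge)
Grazing2   = Ae · Ib · Tk^(T−20) · Biom · Det                   (benthos on detritus)
```

Detritus collects the mortality of the non-benthos guilds and loses settling
`(Serd/D)·(T/20)·Det`, benthos grazing and decomposition `Dr·Det·Tk^(T−20)`.
Water TP gains sediment diffusion `Drr·(Ps−Pw)·(As/D)` and decomposed
detritus, and loses producer uptake and settling `(Serp/D)·Pw`; sediment TP
gains settled biomass and detritus (×0.002), settled TP and benthos mortality
(×0.0001), and loses diffusion.

Chlorine doses are converted to an initial concentration
`C0 = mass × available_fraction / volume`, decay first order
`C(t) = C0·exp(−k·t)` with `k` looked up from a laboratory-fitted table over
C0 = 100–300 mg/L (clamped for lake-scale doses), and enter the ecosystem as
the daily mean of the 24 post-dose hourly values.

Model skill against observations is scored with the Pearson correlation R,
the RMSE-to-observation-SD ratio RSR (<0.5 "very good", 0.5–0.6 "good",
0.6–0.7 "satisfactory") and Willmott's index of agreement IOA ∈ [0, 1].
Parameter influence is ranked by the one-at-a-time mean relative error
`MRE = mean_t |(Pmax(t) − Pmin(t))/Pmax(t)|` between runs at a parameter's
range endpoints.

## Worked example

```python
import chlorolake as cl

# chlorine planning: a 5000 g dose of 30% product in the 8.0e6 L reference volume
c0 = cl.dose_to_concentration(5000, 0.30, 8.0e6)
k = cl.attenuation_rate_for(c0, cl.AttenuationModel())
print(f"C0 = {c0:.4f} mg/L, k = {k} 1/h, "
      f"daily mean = {cl.daily_mean_concentration(c0, k):.6f} mg/L")

# the packaged 199-day season (March 15 .. September 30) with 7 doses
scenario, params = cl.lotus_scenario(seed=1)
traj = cl.simulate(scenario, params)
pw = traj.series("pw")
print(f"water TP peak = {pw.max():.3f} mg/L on day {traj.series('day')[pw.argmax()]:.0f}")

# model skill against noisy synthetic observations
obs = cl.pseudo_observations(traj, noise_sd=0.10, seed=1, components=["pw"])
print(cl.evaluate_components(traj, obs).to_string(index=False))
```

prints

```
C0 = 0.1875 mg/L, k = 2.041 1/h, daily mean = 0.001166 mg/L
water TP peak = 1.649 mg/L on day 87
component  n        R      RSR  RSR_band     IOA
       pw 29 0.994861 0.103931 very good 0.99732
```

The dose arithmetic reproduces the published field concentrations (0.188 and
0.045 mg/L); the daily-mean chlorine after a dose is three orders of
magnitude below C0 because decay at 2.041 h⁻¹ removes most chlorine within
hours — which is why the mortality term carries the ×1000 scale.  The TP
peak lands on the exogenous-pollution pulse day, and the evaluation row shows
the R/RSR/IOA machinery on a series where truth is known.

A command-line interface wraps the same operations:

```sh
chlorolake make-scenario --preset lotus --seed 1 --out runs/lotus
chlorolake simulate --config runs/lotus/scenario.yaml --out runs/lotus
chlorolake chlorine-plan --mass 5000 --fraction 0.30
chlorolake evaluate --traj runs/lotus/trajectory.csv --obs obs.csv
chlorolake sensitivity --config runs/lotus/scenario.yaml \
    --params "c.sk:0.03:0.4,e.maxg:0.5:0.8" --target c
```

Every run writes a `manifest.json` with the config hash, seed, package
version and outputs; re-running a manifest reproduces outputs bit-identically.

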