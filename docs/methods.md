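# Methods

## Model structure and assumptions

`chlorolake` is a zero-dimensional (fully mixed) compartment model of a
small, shallow urban lake, advanced by explicit Euler with a default step of
one day.  The daily step is deliberate: the governing equations are written
as Stella-style daily difference bookkeeping, and the chlorine forcing is
defined as a daily average, so a daily step *is* the model rather than a
numerical approximation of something finer.  Smaller steps are supported
(forcing is interpolated linearly; the daily-mean chlorine constant is held
within each day) and a `refine_check` utility reports step-size convergence.

State variables: biomass density of 14 species, a detritus pool, total
phosphorus in water (`pw`, mg/L) and in sediment (`ps`, mg/g).  Chlorine
concentration is forcing, not state: it is resolved on its own hourly grid
and consumed by the ecosystem as daily means.

Key structural assumptions, inherited from the model family this implements:

- **Guild-scoped biomass units.**  The macrophyte and benthos are g m⁻²
  scale, plankton and periphyton mg L⁻¹-scale densities.  Cross-guild
  couplings (grazing, detritus, phosphorus) combine these numbers *as the
  equations are written*, without unit re-scaling; the only explicit
  conversions are the phosphorus contents 0.002 (per settled
  biomass/detritus) and 0.0001 (per benthos mortality).  Consequently pool
  balances are bookkeeping identities in model units, not closed mass
  budgets, and the `(ps − pw)` diffusion driver subtracts mg/g from mg/L as
  printed.  This is dimensionally suspect but faithful; we flag rather than
  repair it.
- **Monod limitation.**  Producer growth is limited by `pw/(pw+ip)` and
  `sr/(sr+ik)` with a 0/0 → 0 convention.  The tabulated `ip` values carry
  mg m⁻³ day⁻¹ units while `pw` is mg/L; the ratio is evaluated numerically
  as printed.  For some species (notably the macrophyte, ip ≈ 3.4e4) this
  makes phosphorus limitation severe at realistic `pw`; that behaviour comes
  with the printed parameterisation.
- **Chlorine mortality.**  Mortality is amplified by `exp(kcc · cc · M)` with
  M = 1000 for producers and zooplankton and M = 100 for benthos.  Both
  multipliers appear in the source equations; the guild assignment is our
  reading, and each species' multiplier is configurable.  Daily-mean chlorine
  after a realistic dose is ~1e-3 mg/L, so the ×1000 scale brings the
  exponent to order 1 for sensitive species.
- **Prey refuge.**  Zooplankton grazing uses `(Biomphy − 0.5)/(Biomphy +
  kpz)` floored at zero: no grazing below a prey density of 0.5 (the constant
  carries the prey's density units).
- **No fish, bacteria, nitrogen, oxygen or hydrodynamics** — outside the
  model family's scope.

### Grazing bookkeeping

The grazing rate already contains the assimilation efficiency `ae` and (for
zooplankton) the respiratory cost `(1 − rf)`.  Crediting that same quantity
to the grazer while debiting it from the prey would create biomass from
nothing in the bookkeeping sense, so the default mode debits prey (and
detritus) with the *ingested* biomass — assimilated grazing divided by `ae`
and `(1 − rf)` — while grazers gain the assimilated amount.  A
`strict_as_printed=True` switch makes debit equal credit exactly as the
equations are written; the same switch reverts the phosphorus balance to
subtracting raw producer growth and adding raw decomposition instead of
their phosphorus-converted equivalents.  Both modes are tested.

### Diet matrix

The source equations index zooplankton grazing by a single species subscript
without stating which phytoplankton each grazer eats.  The default pairs
every zooplankton species uniformly over the four phytoplankton species
(weights 0.25, rows summing to 1); prey losses are allocated across prey in
proportion to weight × density.  Any other mapping, including one-to-one,
can be supplied.

## Parameters

Defaults are the calibrated 14-species table (species codes a–n).  Where the
table prints a range with a bracketed validation value, the bracketed value
is the default and the range is kept as `SpeciesSpec.ranges` metadata for
sensitivity analysis and calibration.  Three table rows print symbols the
model glossary does not define; they are mapped as follows, and the mapping
is stored in `ParameterSet.metadata` rather than asserted as original
intent: `Iv` → `ip` (phosphorus half-saturation), `Sr` → `ser`
(phytoplankton settling rate, 0.019 day⁻¹), `Pk` → `kpz` for zooplankton
(1.0), with the producer-column `Pk` values retained as metadata only.
A few cells are not individually attributable in the source table; they are
filled guild-wise (respiration 0.01 day⁻¹ for zooplankton, 0.026 day⁻¹ for
benthos; periphyton crowding defaults at the midpoints of their printed
ranges; the chlorine coefficient of *S. acus* set to 0.3 with its printed
range; benthos chlorine coefficients 0, i.e. chlorine-neutral).

Lake configuration (units, default, origin):

| field | default | origin |
|---|---|---|
| depth | 0.8 m | published mean depth |
| reference_volume | 8.0e6 L | reproduces the published dose concentrations 0.188 / 0.045 mg/L exactly (= 8000 m² × 1.0 m, *not* area × mean depth) |
| surface_area | 8000 m² | published |
| active_sediment_layer | 0.05 m | assumed; typical active-layer depth for shallow eutrophic sediments |
| detritus_decomposition_rate | 0.01 day⁻¹ | assumed, literature-plausible |
| phosphorus_diffusion_rate | 0.07 day⁻¹ | assumed, literature-plausible |
| detritus_settling_rate | 0.019 day⁻¹ | matched to the phytoplankton settling rate |
| phosphorus_settling_rate | 0.01 day⁻¹ | assumed |
| p_content_settled / p_content_benthos | 0.002 / 0.0001 | the printed balance constants |

## Chlorine sub-model

A dose of `mass` grams of product with available fraction `f` (0.30 for the
packaged calcium-hypochlorite doses) yields `C0 = mass·f/volume` mg/L.
Decay is first order at a rate taken from the laboratory table (C0 = 100,
150, 200, 250, 300 mg/L → k = 2.041, 0.9161, 1.168, 0.5452, 0.09466 h⁻¹);
three lookup modes exist (nearest row, linear interpolation clamped to the
table range, fixed override).  Lake-scale doses (≤0.19 mg/L) sit far below
the fitted range, so the clamped low-end value 2.041 h⁻¹ applies by default
— an extrapolation we surface rather than hide, with `fixed_k` as the
override.  Residual chlorine from earlier doses is added to a new dose
before the rate is re-selected from the post-dose total; with the packaged
schedule (doses ≥11 days apart, half-lives of minutes) this choice is inert.
The day-*d* mean averages the 24 hourly values after the start of day *d*;
at a midnight boundary carrying the next day's dose, the pre-dose residual
is used so a dose never leaks into the previous day's mean.

`fit_attenuation` regresses ln C on t and reports the decay rate and the
magnitude of the fit's correlation coefficient.

## Simulation engine

Events (doses, phosphorus pulses) apply at the start of their day, before
the derivative evaluation.  After each Euler step the state is clamped at
zero component-wise; the clamp count is recorded on the trajectory and in
run manifests as a model-health signal (the packaged scenario runs with zero
clamps).  Identical scenario + parameters (+ seed) reproduce trajectories
bit-identically.  Trajectories round-trip through wide CSV at 17 significant
digits; loading validates monotone time, completeness and non-negativity and
names the offending row otherwise.

## The packaged scenario and synthetic data

The packaged scenario emulates the study setting structurally: day 0 is
March 15, the horizon 199 days; six 5000 g doses (days 54, 65, 75, 81, 124,
142 — May 8/19/29, June 4, July 17, August 4) and one 1200 g dose (day 166,
August 28); one exogenous TP pulse on day 87 (June 10).  The pulse magnitude
(1.42 mg/L) is a tuning input chosen so the water-TP excursion reaches the
observed ~1.65 mg/L scale; it is not a measurement.

Forcing is synthetic because no temperature or radiance series is published:
sinusoids anchored to the 21.5 °C annual mean, amplitude 6.5 °C, peaking
mid-July (day-of-year 197); radiance 14 ± 6 MJ m⁻² day⁻¹ with the same
phase; optional seeded Gaussian noise, radiance clamped at zero.  Initial
biomasses are labelled assumptions — only the macrophyte planting density
(800 g m⁻²) has a published anchor; other species start at small
early-spring seed densities.

`pseudo_observations` subsamples a trajectory at the field campaign's
cadence (weekly for plankton/periphyton/water, monthly for
macrophyte/benthos/sediment), adds seeded multiplicative noise and floors at
zero.

**What passing tests show — and don't.**  The synthetic scenario supports
structural and qualitative conclusions: dose-day suppression ordered by
chlorine sensitivity, phosphorus pulse propagation from water to sediment,
determinism, conservation identities, metric and calibration machinery.  It
does not reproduce the field trajectories, the per-component skill
statistics, the observed peak-timing of any species, or the published
sensitivity percentages — those depend on the unpublished forcing and
observations.  Under the synthetic forcing the engine-derived sensitivity
ranking places the dominant bloom-former's crowding coefficient first, but
the full ordering differs from the published one for the same reason.

## Numerical choices

- Explicit Euler, dt = 1 day by default; dt must divide the horizon.
- Decay sign: the attenuation exponent is always negative regardless of the
  sign convention a source formula may print.
- MRE denominator: the pointwise value of the max-parameter run; points
  where it is zero contribute zero.  A `denominator="larger"` option uses
  the pointwise larger magnitude of the two runs, making the measure
  symmetric in the endpoint labels.
- RSR band edges classify half-open intervals: a value exactly 0.5 is
  "good", 0.7 "unsatisfactory".
- Sensitivity ranking ties break lexicographically by parameter id.
- Grid calibration is exhaustive over ≤4 parameters and deterministic given
  the grid; it minimises RSR or maximises IOA, averaged over the observed
  components unless a single target is named.

## Known limitations

- The dimensional inconsistencies of the source equations (mg/g vs mg/L in
  diffusion, ip units in the Monod term) are preserved by design; absolute
  pool values should be read as model units, not field predictions.
- Euler at dt = 1 day overshoots during fast blooms; the clamp counter and
  `refine_check` are the guard rails.
- The attenuation table extrapolates two orders of magnitude down in C0 for
  lake-scale doses.
- No parameter estimation from raw laboratory data (not published);
  calibration utilities operate on synthetic observations.
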