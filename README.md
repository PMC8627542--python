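# nitrikin

Nitrification kinetics from dissolved-inorganic-nitrogen (DIN) incubation
time series.

## The problem

Potential nitrification rates of an activated-sludge (or sediment/water)
sample are measured by incubating a slurry in the dark under aeration and
following ammonium (NH₄⁺), nitrite (NO₂⁻) and nitrate (NO₃⁻) every few
hours. Nitrification proceeds in two microbial steps — ammonia oxidation
(AO, NH₄⁺ → NO₂⁻) and nitrite oxidation (NO, NO₂⁻ → NO₃⁻) — and is a
non-linear dynamic process: product curves show a lag phase, an
exponential phase and a plateau. Two- or three-point linear regressions
therefore misestimate the rates badly. `nitrikin` implements the
curve-fitting alternative used in nitrification ecophysiology:

1. **Smooth** the cumulative product series with the four-parameter
   Boltzmann sigmoid

   y(t) = A₂ + (A₁ − A₂) / (1 + e^((t − t₀)/dt))

   fitting NOₓ⁻ = NO₂⁻ + NO₃⁻ for AO and NO₃⁻ for NO.
2. **Average rates** over a window [Tᵢ, T_f] from fitted endpoint values:
   V̄ₐ = ([NOₓ⁻]_final − [NOₓ⁻]_initial)/ΔT and
   V̄ₙ = ([NO₃⁻]_final − [NO₃⁻]_initial)/ΔT (µmol L⁻¹ h⁻¹).
3. **Instantaneous rates** from the analytic first derivative,
   dy/dt = (A₂ − A₁)·eᵘ / (dt·(1 + eᵘ)²) with u = (t − t₀)/dt, whose
   maximum (A₂ − A₁)/(4·dt) is attained exactly at t₀; lag and plateau
   boundaries are where dy/dt crosses a fraction of that maximum
   (closed-form quadratic in eᵘ).
4. **Nitrogen balance**: INB(t) = DIN(t)/DIN(0). INB < 1 flags net
   nitrogen loss (denitrification, anammox, assimilation); INB > 1 flags
   net release by organic-matter mineralization.

A mechanistic two-step nitrification simulator (Monod kinetics, optional
induction ramps, first-order loss, zero-order mineralization, Gaussian
measurement noise) generates incubations with known ground truth, so
every estimator in the package is validated by parameter recovery.

## Who it is for

Microbial ecologists and wastewater-treatment researchers who have
incubation chemistry time series as CSV and want reproducible AO/NO rate
estimates with uncertainties, plus a ground-truthed testbed for the
method itself.

## Worked example

```sh
nitrikin demo sample_A_like --outdir demo_run --seed 42
```

simulates the slow-nitrifier regime (delayed nitrite oxidation, transient
nitrite peak), fits both sigmoids and prints:

```
Nitrification kinetics report
==============================
Boltzmann sigmoid fit — analyte NOx
  n = 12    RSS = 120.889    R² = 0.999584
  param       estimate       std err
  A1          -13.9548         5.052
  A2           499.749         9.476
  t0           39.8986        0.4858
  dt           12.2561        0.5222
  peak rate (A2-A1)/(4·dt) = 10.4785 µmol L⁻¹ h⁻¹ at t0 = 39.9 h
...
Va (NOx): avg 6.667, max 10.479 µmol L⁻¹ h⁻¹ at 39.90 h; lag ends 0.00 h, plateau from 66.00 h
Vn (NO3): avg 5.967, max 12.001 µmol L⁻¹ h⁻¹ at 50.93 h; lag ends 14.05 h, plateau from 66.00 h
INB: final 1.006 (balanced); range [1.000, 1.010]
```

Reading: ammonia oxidation averaged 6.7 µmol L⁻¹ h⁻¹ over the 66-h
window and peaked at 10.5 µmol L⁻¹ h⁻¹ at ~40 h; nitrite oxidation
lagged (inflection 11 h later) but peaked higher — the signature of
induced nitrite oxidizers and the cause of the transient nitrite peak.
INB ≈ 1 throughout: nitrogen was redistributed among pools, not lost.
The run directory holds the fit/rate/INB tables, the resolved config,
the input hash and a log of every default used.

The same works from the library:

```python
import nitrikin as nk

series = nk.read_incubation_csv("incubation.csv")
results = nk.SampleModel(series, nk.AnalysisConfig()).fit()
print(results.summary())
results.rates_table()          # V̄, v_max, t_at_vmax, phase bounds, R²
```

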