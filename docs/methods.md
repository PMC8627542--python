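# Methods

## The sigmoid rate model

Cumulative oxidation-product series from batch nitrification incubations
(NOₓ⁻ = NO₂⁻ + NO₃⁻ tracking ammonia oxidation, NO₃⁻ tracking nitrite
oxidation) are smoothed with the four-parameter Boltzmann sigmoid

    y(t) = A2 + (A1 − A2) / (1 + exp((t − t0)/dt)),

the canonical "Boltzmann" fit of curve-fitting software: A1/A2 are the
initial/final asymptotes (µmol L⁻¹), t0 the inflection time (h) and dt
the slope factor (h). Its derivative is closed-form,

    dy/dt = (A2 − A1)·e^u / (dt·(1 + e^u)²),  u = (t − t0)/dt,

peaking at (A2 − A1)/(4·dt) exactly at t0, which is why all rate
statistics here (average rate, maximum instantaneous rate, phase
boundaries) are analytic rather than numerical. Assumptions: a single
rise from one plateau to another, symmetric about the inflection; no
replicate-level curve heterogeneity (replicates are averaged before
fitting, with an optional 1/SD weighting that is off by default because
no principled weighting scheme exists for three replicates); rates are
attributed chemically, not to guild biomass.

Average rates over a window use the *fitted* endpoint values,
V̄ = (y_fit(T_f) − y_fit(Tᵢ))/ΔT, because the fit is the de-noised
estimate of the trajectory; a raw-endpoint mode (`average_rate_raw`)
exists for comparison. ΔT defaults to the full sampled window and is
configurable — with sigmoidal data the choice matters and should be
reported alongside the estimate.

## Fitting

Trust-region nonlinear least squares (`scipy.optimize.least_squares`)
with data-driven initialization: A1 ← first value, A2 ← last value,
t0 ← first linear-interpolated crossing of (A1+A2)/2 (first crossing
wins when noise creates several), dt ← span/10. Bounds keep A1, A2
within the data range ± one range, t0 within the span ± one span, and
dt ∈ (10⁻⁶, span], which fixes the rising orientation for rising data.
Tolerances: 10⁻¹⁰ on the parameter step, up to 2000 function
evaluations, plus three restarts from ±20 % multiplicatively jittered
starts (seeded); the lowest-cost converged attempt is returned and
non-convergence raises an error carrying the per-restart diagnostics —
a silently unconverged fit is never returned. Parameter covariance is
the Gauss–Newton (JᵀJ)⁻¹·s² estimate; R² is computed on the raw
residuals.

Degenerate inputs are refused explicitly: fewer than five distinct time
points (no residual degree of freedom for four parameters), an all-equal
series (amplitude unidentifiable), dt = 0 in direct evaluation.

## Phase segmentation

Lag end and plateau start are defined as the two times where dy/dt
equals `threshold_frac` (default 0.10) of its maximum. Substituting
r = e^u turns this into r² − (4/f − 2)·r + 1 = 0, whose reciprocal roots
give boundaries symmetric about t0: t0 ± dt·ln r₊. The 10 % default is
a reporting convention, not an estimate; it is exposed everywhere. The
degenerate threshold f = 1 collapses both boundaries onto t0.

## Nitrogen balance

INB(t) = DIN(t)/DIN(0) on replicate means, with DIN = NH₄⁺ + NO₂⁻ +
NO₃⁻ recomputed from the analytes at every call. Values below
1 − tolerance are labelled `loss` (denitrification, anammox,
assimilation — sinks acting on the inorganic pools), above
1 + tolerance `mineralization` (organic-N input), otherwise `balanced`.
The tolerance (default ±0.05) reflects that a ratio of noisy sums
fluctuates around 1 even in a closed system; it is configurable and
recorded in every run log.

## The simulator

The synthetic incubations are the validation substrate for the whole
pipeline, emulating a ~68-h dark aerated slurry incubation sampled every
6 h with n = 3 replicates. Mechanism: a three-pool ODE with Monod
kinetics and fixed maximal rates,

    dNH4/dt = m − v_ao,   dNO2/dt = v_ao − v_no − λ·NO2,
    dNO3/dt = v_no − λ·NO3,
    v_ao = v_ao_max·ramp_ao(t)·NH4/(k_ao + NH4),
    v_no = v_no_max·ramp_no(t)·NO2/(k_no + NO2).

Design choices where the design was genuinely open:

* **Induction ramps.** Each oxidation step may switch on through a
  logistic activity ramp (centre `induction_lag_*`, width `ramp_*`; lag
  0 means fully active). A smooth ramp rather than a hard switch keeps
  the ODE well behaved. Nitrite-oxidizer induction creates the
  transient-nitrite regime. The AO ramp exists because fixed-biomass
  Monod kinetics cannot produce the lag phase real product curves show —
  biomass growth is deliberately not modelled, and the ramp is the
  minimal surrogate for a guild activating during the incubation.
* **Loss acts on NO2⁻ and NO3⁻ only** (λ, h⁻¹): the loss pathways it
  stands for consume oxidized nitrogen. Mineralization is a zero-order
  NH₄⁺ source (µmol L⁻¹ h⁻¹). With both zero, total DIN is conserved to
  solver tolerance — the property INB-based inference relies on.
* **Noise** is additive Gaussian, independent across analytes, times and
  replicates, clipped at zero (SD in µmol L⁻¹). Real measurement error
  is likely heteroscedastic and correlated within a sampling event; the
  simulator does not emulate that, so recovery results bound performance
  under idealized noise only.
* **Integration**: LSODA (stiff-capable, adaptive), rtol 10⁻⁸,
  atol 10⁻¹⁰, with cumulative-oxidation states carried alongside so the
  ground-truth average rates are solver-accurate rather than
  quadrature approximations.

Two presets encode the contrasting regimes: `sample_A_like` (450 µmol
L⁻¹ NH₄⁺, AO ramping at 18 h, NO at 30 h, 68 h / 6 h sampling, noise SD
2, n = 3) yields a sigmoidal NOₓ⁻ curve, a transient nitrite peak
(~117 µmol L⁻¹ near 41 h) and an early-AO/late-NO rate crossover;
`sample_B_like` (120 µmol L⁻¹ NH₄⁺, both steps active from t = 0, NO
capacity 1.5× AO, near-first-order AO with k_ao ≫ NH₄⁺) yields
monotonically declining rates, no nitrite accumulation and rate maxima
at the window start. The B preset runs 12 h sampled hourly: a 6-h
interval over so short an incubation would leave fewer than the five
points a four-parameter fit needs. `closed_system` is the conservation
fixture.

What the simulator does **not** emulate: microbial growth and decay, pH,
temperature or oxygen dependence, spatial/biofilm structure, substrate
inhibition. Passing recovery tests therefore shows the estimators are
correct for saturating-kinetics trajectories under Gaussian noise, not
that the Boltzmann form is the true generative model of any real
incubation — its value on real data is as a smoother whose derivative is
analytic.

## Parameter recovery and problem sizes

Recovery studies use 200 seeded replicates (noise SD 2 µmol L⁻¹ on a
0→100 µmol L⁻¹ sigmoid sampled every 2 h over 80 h, and 200 simulated
sample-A incubations), sizes chosen so the whole suite and the
acceptance script each run in well under a minute while medians are
stable to the second digit. Relative errors of the asymptotes are scaled
by the amplitude A2 − A1 (the lower asymptote's true value is 0, where
a plain relative error is undefined); t0 and dt use ordinary relative
error. Observed medians: < 3 % per parameter, ~1 % for the average AO
rate, ~7 % for the maximum instantaneous rate (the fit's inflection
sharpens slightly relative to the smooth Monod-ramp truth — a model-form
bias, not an estimator bug).

## Known limitations

* The sigmoid is symmetric; strongly asymmetric product curves (e.g.
  substrate inhibition) will bias t0 and the phase boundaries.
* v_max for windows excluding t0 is taken at the nearest endpoint by the
  derivative's unimodality; if a fit places t0 far outside the data the
  reported maximum is an extrapolation of the fitted form.
* INB interpretation assumes the three measured pools are the only
  relevant inorganic nitrogen; organic N is observable only through its
  net effect on the balance.
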