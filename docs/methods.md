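# Methods

## Model structure and assumptions

The dose–INR model is a kinetic-pharmacodynamic (KPD) model: the response is
driven by the dose rate `DR = k10·A` (mg/h) rather than a measured plasma
concentration. The pharmacokinetic part is a single compartment with
first-order elimination and no absorption phase; oral doses are treated as
instantaneous bolus additions to the amount `A`. This is adequate for
warfarin because absorption is fast and nearly complete relative to its
~1.5-day elimination half-life, and because the transit chains smooth the
input further.

Inhibition of coagulation-factor synthesis is a sigmoid in `DR` with
maximum 1 and half-maximal dose rate `EDK50`. We implement the standard
Hill form `Emax·DR^γ/(EDK50^γ + DR^γ)`; with `Emax` fixed at 1 any
alternative placement of the `Emax` exponent is numerically identical.

The delay and shape of the INR response come from two parallel chains of
three transit compartments. The chains share the inhibition input and the
sigmoid parameters and differ only in mean transit time (`MTT1` fast,
`MTT2` slow), reflecting the different half-lives of the affected clotting
factors. Terminal activities map linearly onto INR with equal weights and a
fixed maximal increase `INR_max = 20`. The untreated system is stationary
at `A = 0`, all activities 1, INR = baseline — a property the solver tests
exploit.

A structural consequence worth noting: at steady state the *mean* dose rate
over an interval equals dose/interval regardless of `k10`, so in this model
the maintenance-dose requirement is carried almost entirely by `EDK50`;
`k10` governs onset speed and within-interval fluctuation. The covariate
schema therefore allows genotype and allometric-weight effects on `EDK50`
(as data in the config, not code) in addition to the conventional CL/V
relations — without them, size and genotype would leave the recommended
dose unchanged.

## Parameters and configuration

All population values are data, loaded from a TOML config and validated for
completeness and positivity:

| parameter | units | demo value | role |
|---|---|---|---|
| `tv_cl` / `tv_v` | L/h, L | 0.30, 14 | typical clearance and volume; `k10 = CL/V` ≈ 0.021/h |
| `edk50` by VKORC1 | mg/day (converted to mg/h) | 24 / 17 / 10 for G/G, A/G, A/A | sensitivity; A-allele carriers need less drug |
| CYP2C9 multipliers | – | 1.0 → 0.25/0.30 for \*3/\*3 | reduced clearance and dose requirement for variant alleles |
| `gamma` | – | 2.0 | sigmoid steepness |
| `mtt1`, `mtt2` | h | 29, 118 | transit-chain delays |
| allometric exponents | – | 0.75 (CL, EDK50), 1.0 (V) | size scaling about 70 kg |
| `omega_k10`, `omega_edk50` | variance of log η | 0.0625, 0.09 | between-subject variability (25%, 30% CV) |
| `sigma_add` | INR | 0.15 | additive residual SD |

The demo set is deliberately labelled "not for clinical use": values were
chosen once for physiological plausibility (typical adult dose near
5 mg/day, variant carriers and children lower) and are not published
estimates. Missing covariates default to the most common genotype by
ethnicity (CYP2C9 \*1/\*1; VKORC1 A/G Caucasian/unspecified, A/A Asian,
G/G African), baseline INR 1 and a 24 h dosing interval.

## Numerical choices

- **Integration.** Heun's predictor–corrector (RK2), fixed step, default
  0.1 h. The grid is the union of uniform steps, dose-event times and any
  requested observation times, so read-outs never interpolate across an
  event. When a dose coincides with a grid point the dose is applied first
  and the state recorded after. The inner loop is numba-compiled. Verified
  against the analytic one-compartment decay (<1e-4 relative error at
  h = 0.05) and the Erlang(3, 3/MTT) step response (<1e-4 absolute), with
  measured second-order convergence.
- **Steady state.** The profile counts as periodic when the INR at matched
  phase (16 h post dose, capped at the interval for sub-16 h intervals) of
  consecutive intervals changes by ≤1%. Phase-matched comparison is robust
  to step size. The "steady-state INR" is the trapezoidal mean over the
  final dosing interval.
- **Dose search.** Target is the midpoint of the target range. 100
  repeated doses are simulated per candidate; the search starts at 10 mg,
  brackets by doubling/halving within [0.01, 100] mg per interval, and
  bisects on log-dose until the steady-state mean INR is within ±1% of
  target. Monotonicity of steady-state INR in dose (asserted on a grid)
  makes the solution unique; the result agrees with an exhaustive
  1000-point log-grid search to <1%. Unreachable targets (e.g. baseline
  above target at the minimum dose) raise a diagnostic error; a baseline
  already at target drives the recommendation to the search floor.
- **MAP fit.** The objective is twice the negative log posterior:
  squared-error data term weighted 1/σ² plus η²/ω² prior terms. Powell's
  method runs unbounded from η = (0,0) with one restart from the first
  optimum — Powell resets its direction set on restart, which we found
  necessary in curved valleys where a single bounded run can stall far from
  the optimum; |η| ≥ 3 (a >20-fold deviation) triggers one retry from an
  interior point. Convergence tolerances 1e-8, max 200 iterations per run.
  The curvature is a central finite-difference Hessian (step 1e-4) of half
  the objective, i.e. the Laplace information matrix; its inverse is the η
  covariance used by the prediction band. Observations recorded before the
  first dose inform a missing baseline INR only and never enter the fit.
- **Prediction band.** η is drawn from the Gaussian Laplace approximation
  (Cholesky sampling, seeded), each draw simulated, residual noise
  optionally added to the curves, and pointwise 5th/95th percentiles
  reported with the MAP curve. The residual-inclusive band is the default
  shown to users; the calibration experiment uses the parameter-only band
  (see below).

## What the synthetic generator emulates — and what it does not

`synthetic.draw_patient` samples covariates (age uniform 1–80 y, an
age-linked weight, Caucasian genotype frequencies), draws η from the
between-subject model, doses the patient at their *a priori* typical-dose
recommendation — the realistic monitoring scenario, where observed INRs
deviate from target exactly insofar as the individual deviates from the
typical subject — and emits INRs at scheduled times with additive Gaussian
noise. Two stock designs: *sparse* (7 daily doses, 3 morning INRs —
matching the one-to-three observations per patient typical of early
monitoring) and *rich* (30 days, 20 INRs) for asymptotic checks.

The generator draws truths from the model's own prior, so passing
recovery/coverage tests demonstrates internal consistency of the estimation
machinery — not that real patients follow this model. It does not simulate
adherence lapses, assay or sampling-time errors beyond the additive σ,
vitamin-K intake, interacting drugs, or time-varying covariates.

Experiment sizes: recovery uses 50 rich-design patients with σ = 0.01 (the
small-noise limit; measured bias of both η < 0.005), RMSE monotonicity 25
patients per arm, and band coverage 200 sparse-design patients at the
default σ. Coverage compares the 90% *parameter-uncertainty* band
(residual noise excluded) with the true noise-free INR at the observation
times: with truths drawn from the prior this has nominal coverage for the
exact posterior, so the measured ~90% isolates the quality of the Laplace
approximation. Including residual noise in the band would trivially
over-cover a noise-free truth.

## Known limitations

- Fixed-step explicit integration: extremely short MTTs or pathological
  step choices are the user's responsibility (the defaults are far inside
  the stability region).
- Covariates are fixed at entry; long paediatric simulations do not age the
  patient or mature clearance mid-simulation.
- Only `k10` and `EDK50` carry between-subject variability; MTT and γ are
  population-fixed, so systematic shape misfit folds into the fitted pair.
- The band is a Laplace approximation, not a posterior sample; with very
  sparse, very informative data its tails can deviate from the true
  posterior's.
- No dose-capping or indication-specific target presets; outputs are model
  quantities, not clinical advice.
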