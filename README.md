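# coumadose

Warfarin dose individualization from a mechanism-based model of the INR
response — a library and command-line tool for pharmacometricians and
clinical-pharmacology researchers studying anticoagulant dosing.

Warfarin has a narrow therapeutic window and a more than ten-fold spread in
the maintenance dose patients need. `coumadose` implements a
kinetic-pharmacodynamic (KPD) model of the dose–INR relationship and uses it
two ways:

- **a priori** — before therapy starts, predict the maintenance dose most
  likely to reach a target INR (or the INR response to any given regimen)
  from age, bodyweight, *CYP2C9* and *VKORC1* genotype, baseline and target
  INR;
- **a posteriori** — once doses have been given and INRs observed, estimate
  the patient's individual model parameters by Bayesian (MAP) forecasting
  and tailor the dose to them, with a 90% prediction band.

## The model

Drug amount `A` follows one-compartment first-order elimination, and the
*dose rate* rather than a measured concentration drives the response:

    dA/dt = -k10 · A,        DR = k10 · A            (mg/h)
    EFF   = Emax · DR^γ / (EDK50^γ + DR^γ)           (Emax = 1)

`EFF` is the fractional inhibition of coagulation-factor synthesis; `EDK50`
is the dose rate giving half-maximal inhibition. The delay between dosing
and INR response is carried by two parallel transit-compartment chains
(three compartments each, mean transit times `MTT1`, `MTT2`), both fed by
`(1 − EFF)`:

    dC1_1/dt = (1 − EFF)·3/MTT1 − C1_1·3/MTT1,   …,  dC1_3/dt = C1_2·3/MTT1 − C1_3·3/MTT1

and likewise for chain 2. The predicted INR is

    INR(t) = INR_base + INR_max · (1 − (C1_3 + C2_3)/2),   INR_max = 20.

Before treatment `A = 0` and all activities are 1, so INR equals baseline.
The system is integrated with Heun's second-order Runge–Kutta method; doses
are instantaneous additions to `A`.

Individual parameters are `k10 = CL/V` and `EDK50`, modelled as the
population typical values times `exp(η)` with `η ~ N(0, ω²)`. The MAP
estimate minimizes

    Σ_j (INR_obs,j − INR_pred,j(η))²/σ² + η_k10²/ω²_k10 + η_EDK50²/ω²_EDK50

with Powell's method; a Laplace (Gaussian) approximation at the optimum
yields the 90% prediction band.

**The shipped parameter set is a demo.** Population values live in a TOML
config; the bundled `demo` set is physiologically plausible but *not* a
published, clinically validated estimate (its provenance string says so).
Deployers must transcribe a validated parameter set into the same schema.

## Worked example

A 5-year-old, 20 kg, *CYP2C9* \*2/\*2, *VKORC1* A/A, baseline INR 1.2,
target 2.0–3.0:

```sh
$ coumadose estimate-dose --config demo --age 5 --weight 20 \
    --cyp2c9 '*2/*2' --vkorc1 A/A --baseline-inr 1.2 --target 2:3
mode:               apriori
dose:               0.61 mg/day
                    4.30 mg/week
2.5 mg tablets/wk:  2
steady-state INR:   2.50 (target 2.50)
```

The tool searched for the daily dose whose steady-state mean INR (trapezoid
mean over the final of 100 simulated dosing intervals) equals the midpoint
of the target range to within ±1%, then reports it per day, per week and as
the nearest whole number of 2.5 mg tablets per week.

Predicting the INR for a loading-dose regimen (7.5, 5, 5 mg then 1.5 mg/day
for 12 more days) in a 20-year-old \*3/\*3, A/G adult:

```sh
$ coumadose predict-inr --config demo --age 20 --weight 75 \
    --cyp2c9 '*3/*3' --vkorc1 A/G --baseline-inr 1.0 \
    --dose 1.5 --n-doses 15 --loading 7.5,5,5
predicted INR:      3.45
convention:         INR 16 h after the last dose
```

Because the profile has not yet become periodic (change between doses
> 1%), the reported value is the INR 16 hours after the last dose — the
morning-monitoring convention; at steady state the mean INR over a dosing
interval is reported instead.

With a history file (`type,time,value` rows: covariates, then `dose` and
`inr` records; hours or ISO timestamps):

```sh
coumadose fit --history patient.csv --config demo --band 0.90 --seed 42
coumadose estimate-dose --history patient.csv --config demo   # a posteriori
```

`fit` prints the typical and individual (MAP) `k10` and `EC50`;
`estimate-dose` with observations present tailors the maintenance dose to
the MAP parameters and projects the INR curve from the patient's current
state.

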