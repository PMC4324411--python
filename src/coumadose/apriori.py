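"""A priori maintenance-dose estimation and INR prediction.

Predictions use the typical (population-mean) parameters conditioned on the
patient's covariates, unless explicit individual parameters are supplied
(which is how the a posteriori pathway reuses this module). The dose search
targets the midpoint of the patient's INR target range, simulates 100
repeated administrations to reach steady state, and brackets/bisects on
log-dose until the steady-state mean INR is within +/-1% of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import (
    IndividualParameters,
    ModelState,
    PatientCovariates,
    PopulationModel,
    resolve_missing_covariates,
    typical_parameters,
)
from .solver import DoseEvent, Regimen, Trajectory, integrate

__all__ = [
    "DoseRecommendation",
    "INRPrediction",
    "ConvergenceError",
    "build_regimen",
    "round_to_tablets",
    "detect_steady_state",
    "steady_state_mean_inr",
    "predict_inr",
    "estimate_dose",
]

#: INR read-out time after a dose (h) — morning monitoring convention.
OBSERVATION_PHASE_H = 16.0
#: Number of repeated administrations simulated to ascertain steady state.
N_DOSES_STEADY_STATE = 100
#: Dose-search bounds in mg per dosing interval.
DOSE_BOUNDS = (0.01, 100.0)
#: Relative tolerance on the steady-state mean INR vs target ("target +/- 1%").
TARGET_REL_TOL = 0.01
#: Relative INR change between consecutive doses below which the profile is
#: considered periodic ("steady state").
SS_REL_TOL = 0.01


class ConvergenceError(RuntimeError):
    """The dose search could not reach the target within the dose bounds."""


@dataclass
class DoseRecommendation:
    dose_per_day: float
    dose_per_week: float
    tablets_per_week: int
    trajectory: Trajectory
    achieved_ss_inr: float
    dose_per_interval: float
    interval: float


@dataclass
class INRPrediction:
    value: float
    at_steady_state: bool
    convention: str  # "mean_over_interval" | "sixteen_h_post_dose"
    trajectory: Trajectory


def build_regimen(
    maintenance_dose: float,
    n_doses: int,
    loading_doses: Sequence[float] | None = None,
    interval: float = 24.0,
) -> Regimen:
    """Evenly spaced doses at 0, interval, 2*interval, ...

    The first ``len(loading_doses)`` events take the loading amounts in
    order; the remaining events take the maintenance dose (so a 3-dose
    loading scheme with ``n_doses=15`` yields 12 maintenance doses).
    """
    loading = list(loading_doses or [])
    if n_doses < len(loading):
        raise ValueError(
            f"n_doses ({n_doses}) must cover the {len(loading)} loading doses"
        )
    if maintenance_dose < 0 or any(d < 0 for d in loading):
        raise ValueError("doses must be >= 0")
    amounts = loading + [maintenance_dose] * (n_doses - len(loading))
    events = tuple(DoseEvent(time=i * interval, amount=a) for i, a in enumerate(amounts))
    return Regimen(events=events, dosing_interval=interval)


def round_to_tablets(weekly_dose: float, tablet_strength: float = 2.5) -> int:
    """Nearest whole number of tablets to the weekly dose; .5 ties round up."""
    if weekly_dose < 0:
        raise ValueError("weekly dose must be >= 0")
    return int(math.floor(weekly_dose / tablet_strength + 0.5))


def _phase_for(interval: float) -> float:
    """Post-dose read-out phase: 16 h, or the trough for shorter intervals."""
    return min(OBSERVATION_PHASE_H, interval)


def detect_steady_state(
    traj: Trajectory, interval: float, phase: float | None = None
) -> bool:
    """Has the INR profile become periodic over the dosing interval?

    Compares the INR at matched phase (``phase`` hours post dose, doses
    assumed at 0, interval, 2*interval, ...) of the last two complete
    intervals; true iff the relative change is at most 1%. Phase-matched
    comparison is robust to step size, unlike comparing raw grid maxima.
    """
    if phase is None:
        phase = _phase_for(interval)
    t_end = traj.times[-1]
    n_phases = int(math.floor((t_end - phase) / interval)) + 1
    if n_phases < 2:
        raise ValueError("trajectory must span at least two dosing intervals")
    t_prev = (n_phases - 2) * interval + phase
    t_last = (n_phases - 1) * interval + phase
    inr_prev, inr_last = traj.inr_at(t_prev), traj.inr_at(t_last)
    return abs(inr_last - inr_prev) <= SS_REL_TOL * abs(inr_prev)


def steady_state_mean_inr(
    dose_per_interval: float,
    indiv: IndividualParameters,
    pop: PopulationModel,
    baseline_inr: float,
    interval: float = 24.0,
    *,
    n_doses: int = N_DOSES_STEADY_STATE,
    step: float = 0.1,
    initial_state: ModelState | None = None,
) -> tuple[float, Trajectory]:
    """Mean INR over the final dosing interval after ``n_doses`` doses.

    The mean is a trapezoidal quadrature of the simulated curve over the
    last interval (last dose to last dose + interval).
    """
    regimen = build_regimen(dose_per_interval, n_doses, interval=interval)
    t_last = regimen.last_time
    phase = _phase_for(interval)
    traj = integrate(
        regimen, indiv, pop, baseline_inr, t_end=t_last + interval, step=step,
        initial_state=initial_state,
        extra_times=[t_last - interval + phase, t_last + phase],
    )
    return traj.mean_inr(t_last, t_last + interval), traj


def predict_inr(
    cov: PatientCovariates,
    regimen: Regimen,
    pop: PopulationModel,
    indiv: IndividualParameters | None = None,
    *,
    step: float = 0.1,
    initial_state: ModelState | None = None,
) -> INRPrediction:
    """Predicted INR after the last dose of a regimen.

    If the steady-state criterion holds over the final interval, the value
    is the time-averaged INR over that interval; otherwise it is the INR
    16 hours after the last dose (the morning-monitoring convention). The
    ``convention`` field records which was used.
    """
    if not regimen.events:
        raise ValueError("regimen must contain at least one dose event")
    cov = resolve_missing_covariates(cov)
    if indiv is None:
        indiv = typical_parameters(cov, pop)
    interval = regimen.dosing_interval
    t_last = regimen.last_time
    phase = _phase_for(interval)
    traj = integrate(
        regimen, indiv, pop, cov.baseline_inr, t_end=t_last + interval, step=step,
        initial_state=initial_state,
        extra_times=[t_last + phase],
    )
    if regimen.total_dose == 0.0 and initial_state is None:
        # untreated: curve is flat at baseline; report it as such
        return INRPrediction(float(cov.baseline_inr), False,
                             "sixteen_h_post_dose", traj)
    at_ss = (
        traj.times[-1] >= 2 * interval
        and detect_steady_state(traj, interval)
    )
    if at_ss:
        value = traj.mean_inr(t_last, t_last + interval)
        convention = "mean_over_interval"
    else:
        value = traj.inr_at(t_last + phase)
        convention = "sixteen_h_post_dose"
    return INRPrediction(float(value), at_ss, convention, traj)


def estimate_dose(
    cov: PatientCovariates,
    pop: PopulationModel,
    indiv: IndividualParameters | None = None,
    *,
    step: float = 0.1,
    initial_state: ModelState | None = None,
) -> DoseRecommendation:
    """Maintenance dose whose steady-state mean INR hits the target midpoint.

    Starts from 10 mg per interval, brackets the target by doubling or
    halving within [0.01, 100] mg, then bisects on log-dose until the
    steady-state mean INR (trapezoidal mean over the final of 100 dosing
    intervals) is within +/-1% of the midpoint of the target range. The
    steady-state mean INR is strictly increasing in dose, so the solution
    is unique.
    """
    cov = resolve_missing_covariates(cov)
    if indiv is None:
        indiv = typical_parameters(cov, pop)
    interval = float(cov.dosing_interval)
    baseline = float(cov.baseline_inr)
    target = cov.target_mid
    tol = TARGET_REL_TOL * target
    lo_bound, hi_bound = DOSE_BOUNDS

    def ss_inr(d: float) -> tuple[float, Trajectory]:
        return steady_state_mean_inr(
            d, indiv, pop, baseline, interval, step=step,
            initial_state=initial_state,
        )

    dose = 10.0
    inr, traj = ss_inr(dose)
    # bracket [lo, hi] with f(lo) <= target <= f(hi)
    lo = hi = dose
    inr_lo = inr_hi = inr
    while inr_lo > target and lo > lo_bound:
        lo = max(lo / 2.0, lo_bound)
        inr_lo, traj = ss_inr(lo)
    while inr_hi < target and hi < hi_bound:
        hi = min(hi * 2.0, hi_bound)
        inr_hi, traj = ss_inr(hi)

    if inr_lo > target + tol:
        raise ConvergenceError(
            f"steady-state INR at the minimum dose {lo_bound} mg is "
            f"{inr_lo:.3f}, above target {target:.3f} +/- 1% "
            "(baseline INR may already exceed the target)"
        )
    if inr_hi < target - tol:
        raise ConvergenceError(
            f"steady-state INR at the maximum dose {hi_bound} mg is "
            f"{inr_hi:.3f}, below target {target:.3f} +/- 1%"
        )

    # choose the bracket end closer to target as the running best
    if abs(inr_lo - target) <= abs(inr_hi - target):
        dose, inr = lo, inr_lo
    else:
        dose, inr = hi, inr_hi
    for _ in range(60):
        if abs(inr - target) <= tol:
            break
        mid = math.sqrt(lo * hi)
        inr_mid, _ = ss_inr(mid)
        if inr_mid < target:
            lo, inr_lo = mid, inr_mid
        else:
            hi, inr_hi = mid, inr_mid
        dose, inr = mid, inr_mid
    if abs(inr - target) > tol:
        raise ConvergenceError(
            f"bisection stalled at dose {dose:.4f} mg (INR {inr:.3f}, "
            f"target {target:.3f})"
        )
    # re-simulate at the accepted dose so the reported curve matches it
    inr, traj = ss_inr(dose)

    dose_per_day = dose * 24.0 / interval
    dose_per_week = 7.0 * dose_per_day
    return DoseRecommendation(
        dose_per_day=dose_per_day,
        dose_per_week=dose_per_week,
        tablets_per_week=round_to_tablets(dose_per_week),
        trajectory=traj,
        achieved_ss_inr=float(inr),
        dose_per_interval=dose,
        interval=interval,
    )
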