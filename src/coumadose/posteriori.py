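"""Bayesian (MAP / empirical-Bayes) individualization from observed INRs.

The individual parameters (k10, EDK50) are modelled as the population
typical values times exp(eta), with eta a pair of zero-mean Gaussian
random effects (variances omega_k10, omega_edk50). Given a patient's dosing
history and INR observations, the MAP estimate minimizes

    sum_j (INR_obs_j - INR_pred_j(eta))^2 / sigma^2
        + eta_k10^2 / omega_k10 + eta_edk50^2 / omega_edk50

over eta using Powell's derivative-free method. The objective is twice the
negative log posterior up to constants, so the Laplace covariance is the
inverse Hessian of half of it; that Gaussian approximation drives the 90%
prediction band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .apriori import DoseRecommendation, estimate_dose
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
    "INRObservation",
    "PatientHistory",
    "IndividualEstimate",
    "PredictionBand",
    "FitError",
    "map_objective",
    "fit_individual",
    "estimate_dose_individual",
    "predict_band",
]

log = logging.getLogger(__name__)

_PENALTY = 1e10
_ETA_BOX = 3.0  # search box for log-scale deviations (|eta| <= 3 ~ 20-fold)


class FitError(RuntimeError):
    """Optimizer failed; carries the best estimate found so far."""

    def __init__(self, message: str, best: "IndividualEstimate | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class INRObservation:
    """One INR measurement: time in hours since the first dose, and value."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if not self.value > 0:
            raise ValueError("INR value must be > 0")


@dataclass(frozen=True)
class PatientHistory:
    """Covariates plus the recorded doses and INR observations."""

    covariates: PatientCovariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[INRObservation, ...] = ()

    def __post_init__(self) -> None:
        for seq, what in ((self.doses, "dose"), (self.observations, "observation")):
            times = [e.time for e in seq]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"{what} times must be non-decreasing")

    @property
    def first_dose_time(self) -> float:
        if not self.doses:
            raise ValueError("history contains no doses")
        return self.doses[0].time

    @property
    def end_time(self) -> float:
        t = self.doses[-1].time if self.doses else 0.0
        if self.observations:
            t = max(t, self.observations[-1].time)
        return t

    def fit_observations(self) -> tuple[INRObservation, ...]:
        """Observations on or after the first dose — the ones entering the fit."""
        t0 = self.first_dose_time
        return tuple(o for o in self.observations if o.time >= t0)

    def resolved_covariates(self) -> PatientCovariates:
        """Resolve defaults; pre-first-dose INRs inform a missing baseline."""
        cov = self.covariates
        if cov.baseline_inr is None and self.doses:
            t0 = self.first_dose_time
            pre = [o.value for o in self.observations if o.time < t0]
            if pre:
                cov = replace(cov, baseline_inr=float(np.mean(pre)))
        return resolve_missing_covariates(cov)


@dataclass
class IndividualEstimate:
    """MAP fit result: parameters, deviations, curvature and objective."""

    map_params: IndividualParameters
    typical_params: IndividualParameters
    eta: np.ndarray  # (eta_k10, eta_edk50)
    curvature: np.ndarray  # 2x2 information matrix (Hessian of half-objective)
    objective_value: float


@dataclass
class PredictionBand:
    times: np.ndarray
    lower: np.ndarray
    point: np.ndarray  # MAP curve
    upper: np.ndarray


def _history_regimen(history: PatientHistory) -> Regimen:
    cov = history.resolved_covariates()
    return Regimen(events=history.doses, dosing_interval=float(cov.dosing_interval))


def _predict_at_observations(
    eta: np.ndarray,
    history: PatientHistory,
    pop: PopulationModel,
    typical: IndividualParameters,
    obs_times: np.ndarray,
    baseline: float,
    step: float,
) -> np.ndarray:
    indiv = typical.scaled(float(eta[0]), float(eta[1]))
    t_end = max(history.end_time, float(obs_times.max()) if obs_times.size else 0.0)
    traj = integrate(
        _history_regimen(history), indiv, pop, baseline, t_end=t_end,
        step=step, extra_times=obs_times,
    )
    return np.asarray(traj.inr_at(obs_times), float)


def map_objective(
    eta,
    history: PatientHistory,
    pop: PopulationModel,
    *,
    step: float = 0.1,
) -> float:
    """MAP objective (twice the negative log posterior, up to constants).

    With no usable observations this degenerates to the prior term alone,
    minimized at eta = 0. Non-finite predictions yield a large penalty so
    the derivative-free search backs away.
    """
    eta = np.asarray(eta, float)
    prior = eta[0] ** 2 / pop.omega_k10 + eta[1] ** 2 / pop.omega_edk50
    obs = history.fit_observations()
    if not obs:
        return float(prior)
    cov = history.resolved_covariates()
    typical = typical_parameters(cov, pop)
    obs_times = np.array([o.time for o in obs], float)
    obs_values = np.array([o.value for o in obs], float)
    pred = _predict_at_observations(
        eta, history, pop, typical, obs_times, float(cov.baseline_inr), step
    )
    if not np.all(np.isfinite(pred)):
        log.warning("non-finite INR prediction at eta=%s; penalizing", eta)
        return _PENALTY
    sd = np.array([pop.residual_sd(p) for p in pred])
    data = float(np.sum(((obs_values - pred) / sd) ** 2))
    return data + float(prior)


def _fd_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian, symmetrized."""
    n = len(x)
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            fij = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h**2)
            hess[i, j] = hess[j, i] = fij
    return 0.5 * (hess + hess.T)


def fit_individual(
    history: PatientHistory,
    pop: PopulationModel,
    *,
    step: float = 0.1,
    maxiter: int = 200,
) -> IndividualEstimate:
    """MAP estimate of (k10, edk50) from the history's doses and INRs.

    Powell's method from eta = (0, 0) within |eta| <= 3; if the first run
    terminates on the box edge, restart once from a perturbed interior
    point. The curvature is a central finite-difference Hessian of half the
    objective at the optimum (the Laplace information matrix).
    """
    cov = history.resolved_covariates()
    typical = typical_parameters(cov, pop)

    obj = lambda e: map_objective(e, history, pop, step=step)

    def run(x0: np.ndarray):
        return optimize.minimize(
            obj, x0, method="Powell",
            options={"xtol": 1e-8, "ftol": 1e-8, "maxiter": maxiter},
        )

    res = run(np.zeros(2))
    # Powell resets its direction set on restart; one polish run from the
    # first optimum guards against premature termination in curved valleys
    res2 = run(res.x)
    if res2.fun <= res.fun:
        res = res2
    if np.any(np.abs(res.x) >= _ETA_BOX):
        # implausibly large deviation (> 20-fold): retry from an interior point
        res3 = run(np.clip(res.x, -_ETA_BOX + 0.2, _ETA_BOX - 0.2) + 0.1)
        if res3.fun < res.fun:
            res = res3

    eta = np.asarray(res.x, float)
    curvature = _fd_hessian(lambda e: 0.5 * obj(e), eta)
    estimate = IndividualEstimate(
        map_params=typical.scaled(float(eta[0]), float(eta[1])),
        typical_params=typical,
        eta=eta,
        curvature=curvature,
        objective_value=float(res.fun),
    )
    if not res.success and res.fun > obj(np.zeros(2)) + 1e-9:
        raise FitError(f"Powell search did not converge: {res.message}", estimate)
    return estimate


def fitted_trajectory(
    estimate: IndividualEstimate,
    history: PatientHistory,
    pop: PopulationModel,
    *,
    step: float = 0.1,
    t_end: float | None = None,
) -> Trajectory:
    """Simulate the recorded history at the MAP parameters."""
    cov = history.resolved_covariates()
    if t_end is None:
        t_end = history.end_time
    return integrate(
        _history_regimen(history), estimate.map_params, pop,
        float(cov.baseline_inr), t_end=max(t_end, history.end_time), step=step,
    )


def estimate_dose_individual(
    estimate: IndividualEstimate,
    history: PatientHistory,
    pop: PopulationModel,
    *,
    step: float = 0.1,
) -> DoseRecommendation:
    """Tailored maintenance dose from the MAP parameters.

    Reuses the a priori dose search with the individual parameters, but the
    projection starts from the model state at the end of the fitted history
    ("Day 0"), so the reported curve continues the patient's current
    anticoagulation status rather than restarting from baseline.
    """
    cov = history.resolved_covariates()
    current = fitted_trajectory(estimate, history, pop, step=step).terminal_state()
    return estimate_dose(
        cov, pop, indiv=estimate.map_params, step=step, initial_state=current
    )


def predict_band(
    estimate: IndividualEstimate,
    regimen: Regimen,
    pop: PopulationModel,
    level: float = 0.90,
    n_draws: int = 500,
    seed: int = 0,
    *,
    baseline_inr: float = 1.0,
    initial_state: ModelState | None = None,
    t_end: float | None = None,
    step: float = 0.1,
    include_residual: bool = True,
) -> PredictionBand:
    """Pointwise prediction band from the Laplace approximation.

    Draws eta from a Gaussian centred at the MAP estimate with covariance
    equal to the inverse curvature, simulates each draw over the regimen,
    optionally adds residual noise (SD sigma) to every simulated curve, and
    returns the pointwise (1-level)/2 and (1+level)/2 percentiles together
    with the MAP curve. Fully reproducible for a fixed seed.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    try:
        chol_info = np.linalg.cholesky(estimate.curvature)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "curvature matrix is not positive definite; the fit is "
            "under-determined — add more INR observations"
        ) from exc
    cov_eta = np.linalg.inv(chol_info.T) @ np.linalg.inv(chol_info)

    if t_end is None:
        t_end = regimen.last_time + regimen.dosing_interval
    rng = np.random.default_rng(seed)
    etas = rng.multivariate_normal(estimate.eta, cov_eta, size=n_draws,
                                   method="cholesky")
    point_traj = integrate(
        regimen, estimate.map_params, pop, baseline_inr, t_end=t_end,
        step=step, initial_state=initial_state,
    )
    times = point_traj.times
    curves = np.empty((n_draws, times.size))
    for i, (ek, ee) in enumerate(etas):
        indiv = estimate.typical_params.scaled(float(ek), float(ee))
        traj = integrate(
            regimen, indiv, pop, baseline_inr, t_end=t_end, step=step,
            initial_state=initial_state,
        )
        curves[i] = traj.inr
    if include_residual:
        sd = np.vectorize(pop.residual_sd)(curves) if pop.residual_model == "proportional" \
            else pop.sigma_add
        curves = curves + rng.normal(0.0, 1.0, curves.shape) * sd
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    lower = np.percentile(curves, lo_q, axis=0)
    upper = np.percentile(curves, hi_q, axis=0)
    return PredictionBand(times=times, lower=lower, point=point_traj.inr, upper=upper)
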