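"""MAP estimation, individualized dosing and the Laplace prediction band."""

import dataclasses

import numpy as np
import pytest

from coumadose import apriori
from coumadose.model_core import resolve_missing_covariates, typical_parameters
from coumadose.posteriori import (
    INRObservation,
    PatientHistory,
    estimate_dose_individual,
    fit_individual,
    fitted_trajectory,
    map_objective,
    predict_band,
)
from coumadose.solver import Regimen, integrate


def _noise_free_history(cov, pop, eta, n_doses=30, obs_days=None):
    """Doses at the typical a priori dose; observations from typical*exp(eta)."""
    cov = resolve_missing_covariates(cov)
    typical = typical_parameters(cov, pop)
    dose = apriori.estimate_dose(cov, pop, indiv=typical).dose_per_interval
    reg = apriori.build_regimen(dose, n_doses)
    if obs_days is None:
        obs_days = range(1, 21)
    obs_t = np.array([24.0 * d + 16.0 for d in obs_days])
    truth = typical.scaled(*eta)
    traj = integrate(reg, truth, pop, float(cov.baseline_inr),
                     t_end=max(reg.last_time + 24.0, obs_t.max()),
                     extra_times=obs_t)
    obs = tuple(INRObservation(float(t), float(v))
                for t, v in zip(obs_t, traj.inr_at(obs_t)))
    return PatientHistory(covariates=cov, doses=reg.events, observations=obs)


class TestMapObjective:
    def test_zero_at_truth_with_noise_free_data(self, small_noise_demo, adult_cov):
        # observations generated at the typical parameters, eta = 0
        hist = _noise_free_history(adult_cov, small_noise_demo, (0.0, 0.0))
        assert map_objective((0.0, 0.0), hist, small_noise_demo) == pytest.approx(
            0.0, abs=1e-6)

    def test_prior_only_without_observations(self, demo_pop, adult_cov):
        cov = resolve_missing_covariates(adult_cov)
        reg = apriori.build_regimen(5.0, 7)
        hist = PatientHistory(covariates=cov, doses=reg.events, observations=())
        eta = (0.3, -0.2)
        expected = 0.3**2 / demo_pop.omega_k10 + 0.2**2 / demo_pop.omega_edk50
        assert map_objective(eta, hist, demo_pop) == pytest.approx(expected)
        assert map_objective((0.0, 0.0), hist, demo_pop) == 0.0

    def test_data_term_scales_inversely_with_sigma_squared(self, demo_pop,
                                                           adult_cov):
        hist = _noise_free_history(adult_cov, demo_pop, (0.2, 0.1),
                                   obs_days=[3, 7, 14])
        eta = (0.0, 0.0)
        prior = 0.0
        pop2 = dataclasses.replace(demo_pop, sigma_add=2 * demo_pop.sigma_add)
        data1 = map_objective(eta, hist, demo_pop) - prior
        data2 = map_objective(eta, hist, pop2) - prior
        assert data2 == pytest.approx(data1 / 4.0, rel=1e-12)


class TestFitIndividual:
    def test_no_observations_returns_typical(self, demo_pop, adult_cov):
        cov = resolve_missing_covariates(adult_cov)
        reg = apriori.build_regimen(5.0, 7)
        hist = PatientHistory(covariates=cov, doses=reg.events, observations=())
        est = fit_individual(hist, demo_pop)
        assert est.map_params.k10 == pytest.approx(est.typical_params.k10, rel=1e-4)
        assert est.map_params.edk50 == pytest.approx(est.typical_params.edk50,
                                                     rel=1e-4)
        # prior-only curvature equals the prior precision
        assert est.curvature[0, 0] == pytest.approx(1 / demo_pop.omega_k10, rel=1e-3)

    def test_recovers_known_deviation_from_rich_noise_free_data(
            self, small_noise_demo, adult_cov):
        true_eta = (0.3, -0.4)
        hist = _noise_free_history(adult_cov, small_noise_demo, true_eta)
        est = fit_individual(hist, small_noise_demo)
        assert abs(est.eta[0] - true_eta[0]) < 0.02
        assert abs(est.eta[1] - true_eta[1]) < 0.02

    def test_tight_prior_shrinks_to_typical(self, demo_pop, adult_cov):
        pop = dataclasses.replace(demo_pop, omega_k10=1e-6, omega_edk50=1e-6)
        hist = _noise_free_history(adult_cov, pop, (0.3, -0.4),
                                   obs_days=[3, 7, 14])
        est = fit_individual(hist, pop)
        assert np.abs(est.eta).max() < 5e-3

    def test_optimizer_never_loses_to_prior_mode(self, demo_pop, adult_cov):
        hist = _noise_free_history(adult_cov, demo_pop, (0.5, 0.3),
                                   obs_days=[2, 5, 9])
        est = fit_individual(hist, demo_pop)
        assert est.objective_value <= map_objective((0.0, 0.0), hist, demo_pop) + 1e-9

    def test_fit_then_predict_reproduces_noise_free_data(self, small_noise_demo,
                                                         adult_cov):
        hist = _noise_free_history(adult_cov, small_noise_demo, (0.2, -0.3))
        est = fit_individual(hist, small_noise_demo)
        traj = fitted_trajectory(est, hist, small_noise_demo)
        obs_t = np.array([o.time for o in hist.observations])
        obs_v = np.array([o.value for o in hist.observations])
        assert np.abs(traj.inr_at(obs_t) - obs_v).max() < 5e-3

    def test_more_observations_less_shrinkage(self, demo_pop, adult_cov):
        true_eta = (0.25, -0.30)
        sparse = _noise_free_history(adult_cov, demo_pop, true_eta,
                                     obs_days=[3, 5, 7])
        rich = _noise_free_history(adult_cov, demo_pop, true_eta)
        e_sparse = fit_individual(sparse, demo_pop).eta
        e_rich = fit_individual(rich, demo_pop).eta
        # MAP deviations grow from 0 (no data) toward the truth as data accrue
        assert 0 < np.linalg.norm(e_sparse) <= np.linalg.norm(e_rich) + 1e-6
        assert np.linalg.norm(e_rich) <= np.linalg.norm(true_eta) + 0.02


class TestEstimateDoseIndividual:
    def test_no_observations_matches_apriori(self, demo_pop, adult_cov):
        cov = resolve_missing_covariates(adult_cov)
        reg = apriori.build_regimen(5.0, 7)
        hist = PatientHistory(covariates=cov, doses=reg.events, observations=())
        est = fit_individual(hist, demo_pop)
        rec_ind = estimate_dose_individual(est, hist, demo_pop)
        rec_apriori = apriori.estimate_dose(cov, demo_pop)
        assert rec_ind.dose_per_day == pytest.approx(rec_apriori.dose_per_day,
                                                     rel=0.02)

    def test_sensitive_patient_gets_lower_dose(self, small_noise_demo, adult_cov):
        # eta_edk50 < 0: half-maximal inhibition at a lower dose rate
        hist = _noise_free_history(adult_cov, small_noise_demo, (0.0, -0.5))
        est = fit_individual(hist, small_noise_demo)
        rec_ind = estimate_dose_individual(est, hist, small_noise_demo)
        rec_apriori = apriori.estimate_dose(
            resolve_missing_covariates(adult_cov), small_noise_demo)
        assert rec_ind.dose_per_day < rec_apriori.dose_per_day

    def test_projection_continues_from_current_inr(self, demo_pop, adult_cov):
        hist = _noise_free_history(adult_cov, demo_pop, (0.1, -0.2),
                                   obs_days=[3, 5, 7], n_doses=7)
        est = fit_individual(hist, demo_pop)
        rec = estimate_dose_individual(est, hist, demo_pop)
        fitted_end = fitted_trajectory(est, hist, demo_pop).inr[-1]
        # dose events change the amount only; INR is continuous at Day 0
        assert rec.trajectory.inr[0] == pytest.approx(fitted_end, abs=1e-9)


class TestPredictBand:
    def _fit(self, pop, cov, eta=(0.2, -0.2)):
        hist = _noise_free_history(cov, pop, eta, obs_days=[3, 7, 14])
        return fit_individual(hist, pop), hist

    def test_seeded_band_is_bit_reproducible(self, demo_pop, adult_cov):
        est, hist = self._fit(demo_pop, adult_cov)
        reg = Regimen(events=hist.doses)
        b1 = predict_band(est, reg, demo_pop, seed=7, baseline_inr=1.0,
                          n_draws=100)
        b2 = predict_band(est, reg, demo_pop, seed=7, baseline_inr=1.0,
                          n_draws=100)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)

    def test_map_curve_inside_band(self, demo_pop, adult_cov):
        est, hist = self._fit(demo_pop, adult_cov)
        reg = Regimen(events=hist.doses)
        band = predict_band(est, reg, demo_pop, seed=3, baseline_inr=1.0,
                            n_draws=200)
        assert (band.lower <= band.point + 1e-9).all()
        assert (band.point <= band.upper + 1e-9).all()

    def test_band_collapses_without_uncertainty(self, demo_pop, adult_cov):
        est, hist = self._fit(demo_pop, adult_cov)
        tight = dataclasses.replace(est, curvature=np.eye(2) * 1e12)
        pop = dataclasses.replace(demo_pop, sigma_add=1e-9)
        reg = Regimen(events=hist.doses)
        band = predict_band(tight, reg, pop, seed=5, baseline_inr=1.0,
                            n_draws=200)
        assert np.max(band.upper - band.lower) < 1e-3

    def test_singular_curvature_rejected(self, demo_pop, adult_cov):
        est, hist = self._fit(demo_pop, adult_cov)
        singular = dataclasses.replace(est, curvature=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="observations"):
            predict_band(singular, Regimen(events=hist.doses), demo_pop,
                         seed=1, baseline_inr=1.0)
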