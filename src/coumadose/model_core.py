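"""Structural warfarin KPD model: states, parameters, covariates and the INR output.

The model is a kinetic-pharmacodynamic (KPD) model: a one-compartment drug
amount ``A`` with first-order elimination drives a dose rate ``DR = k10*A``
(mg/h), which inhibits coagulation-factor synthesis through a sigmoid
inhibition function. The inhibition feeds two parallel transit-compartment
chains (three compartments each, mean transit times ``mtt1`` and ``mtt2``)
whose terminal activities determine the predicted INR:

    INR(t) = INR_base + INR_max * (1 - (C1_3(t) + C2_3(t)) / 2)

Before treatment A = 0 and every activity equals 1, so INR equals baseline.
This module holds only the state equations and covariate handling; numerical
integration lives in :mod:`coumadose.solver` and estimation in
:mod:`coumadose.posteriori`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "CYP2C9_GENOTYPES",
    "VKORC1_GENOTYPES",
    "ETHNICITIES",
    "PatientCovariates",
    "CovariateRelations",
    "PopulationModel",
    "IndividualParameters",
    "ModelState",
    "resolve_missing_covariates",
    "typical_parameters",
    "effect",
    "state_derivative",
    "inr_from_state",
]

CYP2C9_GENOTYPES = ("*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3")
VKORC1_GENOTYPES = ("G/G", "A/G", "A/A")
ETHNICITIES = ("Caucasian", "Asian", "African", "unspecified")

#: Most common VKORC1 genotype conditioned on ethnicity, used when the
#: genotype is not reported. A/G is intermediate, A/A low and G/G high
#: dose requirement.
_VKORC1_DEFAULT_BY_ETHNICITY = {
    "Caucasian": "A/G",
    "unspecified": "A/G",
    "Asian": "A/A",
    "African": "G/G",
}


class ConfigurationError(ValueError):
    """A population-model configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics, genotypes and INR targets for one patient.

    ``cyp2c9``, ``vkorc1`` and ``baseline_inr`` may be ``None`` (missing);
    :func:`resolve_missing_covariates` fills them with the documented
    defaults before any prediction.
    """

    age: float
    weight: float
    cyp2c9: str | None = None
    vkorc1: str | None = None
    ethnicity: str = "unspecified"
    baseline_inr: float | None = None
    target_low: float = 2.0
    target_high: float = 3.0
    dosing_interval: float | None = 24.0

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.cyp2c9 is not None and self.cyp2c9 not in CYP2C9_GENOTYPES:
            raise ValueError(f"unknown CYP2C9 genotype {self.cyp2c9!r}")
        if self.vkorc1 is not None and self.vkorc1 not in VKORC1_GENOTYPES:
            raise ValueError(f"unknown VKORC1 genotype {self.vkorc1!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.baseline_inr is not None and self.baseline_inr < 0.8:
            raise ValueError("baseline INR below 0.8 is not physiological")
        if not self.target_low < self.target_high:
            raise ValueError("target_low must be < target_high")

    @property
    def target_mid(self) -> float:
        return 0.5 * (self.target_low + self.target_high)

    @property
    def resolved(self) -> bool:
        return (
            self.cyp2c9 is not None
            and self.vkorc1 is not None
            and self.baseline_inr is not None
            and self.dosing_interval is not None
        )


def resolve_missing_covariates(cov: PatientCovariates) -> PatientCovariates:
    """Fill missing covariates with the tool's documented defaults.

    Missing CYP2C9 becomes ``*1/*1`` (the genotype with the highest dose
    requirement); missing VKORC1 becomes the most common genotype for the
    patient's ethnicity (A/G for Caucasians and unspecified, A/A for Asians,
    G/G for Africans); missing baseline INR becomes 1.0 and a missing dosing
    interval 24 h. Present values are never touched.
    """
    updates: dict = {}
    if cov.cyp2c9 is None:
        updates["cyp2c9"] = "*1/*1"
    if cov.vkorc1 is None:
        updates["vkorc1"] = _VKORC1_DEFAULT_BY_ETHNICITY[cov.ethnicity]
    if cov.baseline_inr is None:
        updates["baseline_inr"] = 1.0
    if cov.dosing_interval is None:
        updates["dosing_interval"] = 24.0
    return replace(cov, **updates) if updates else cov


@dataclass(frozen=True)
class CovariateRelations:
    """Coefficients mapping covariates onto CL, V and EDK50.

    All relations are data, not code: allometric weight scaling about
    ``ref_weight``, an exponential age decline on clearance about
    ``ref_age``, per-CYP2C9 multipliers on clearance, and (optionally)
    per-CYP2C9 and allometric-weight multipliers on EDK50.
    """

    ref_weight: float = 70.0
    ref_age: float = 50.0
    cl_weight_exp: float = 0.75
    v_weight_exp: float = 1.0
    cl_age_slope: float = 0.0  # per-year exponential decline of CL
    cyp2c9_cl_mult: Mapping[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in CYP2C9_GENOTYPES}
    )
    edk50_weight_exp: float = 0.0
    cyp2c9_edk50_mult: Mapping[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in CYP2C9_GENOTYPES}
    )


@dataclass(frozen=True)
class PopulationModel:
    """Typical parameter values, covariate relations and variability terms.

    ``edk50_by_vkorc1`` is stored in mg/h (the internal time base is hours);
    the config loader converts per-day entries. ``omega_k10`` and
    ``omega_edk50`` are the variances of the log-scale between-subject
    random effects; ``sigma_add`` is the residual SD on the INR scale.
    """

    tv_cl: float
    tv_v: float
    edk50_by_vkorc1: Mapping[str, float]
    gamma: float
    mtt1: float
    mtt2: float
    omega_k10: float
    omega_edk50: float
    sigma_add: float
    emax: float = 1.0
    n_transit: int = 3
    inr_max: float = 20.0
    residual_model: str = "additive"
    covariate_relations: CovariateRelations = field(default_factory=CovariateRelations)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("tv_cl", "tv_v", "gamma", "mtt1", "mtt2",
                     "omega_k10", "omega_edk50", "sigma_add", "emax", "inr_max"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_transit != 3:
            raise ConfigurationError("the transit chains are fixed at 3 compartments")
        if self.residual_model not in ("additive", "proportional"):
            raise ConfigurationError(f"unknown residual model {self.residual_model!r}")
        missing = [g for g in VKORC1_GENOTYPES if g not in self.edk50_by_vkorc1]
        if missing:
            raise ConfigurationError(f"edk50_by_vkorc1 missing genotype(s): {missing}")
        for g, v in self.edk50_by_vkorc1.items():
            if not v > 0:
                raise ConfigurationError(f"edk50 for {g} must be > 0, got {v}")

    def residual_sd(self, inr: float) -> float:
        """Residual SD at a given INR (additive by default)."""
        if self.residual_model == "proportional":
            return self.sigma_add * inr
        return self.sigma_add


@dataclass(frozen=True)
class IndividualParameters:
    """The (k10, edk50) pair actually used to simulate one subject.

    ``k10`` is the first-order elimination rate constant CL/V (1/h);
    ``edk50`` the dose rate giving half-maximal inhibition (mg/h).
    """

    k10: float
    edk50: float

    def __post_init__(self) -> None:
        if not (self.k10 > 0 and self.edk50 > 0):
            raise ValueError("k10 and edk50 must both be > 0")

    def scaled(self, eta_k10: float, eta_edk50: float) -> "IndividualParameters":
        """Apply log-scale deviations: parameter * exp(eta)."""
        return IndividualParameters(
            k10=self.k10 * math.exp(eta_k10),
            edk50=self.edk50 * math.exp(eta_edk50),
        )


def typical_parameters(cov: PatientCovariates, pop: PopulationModel) -> IndividualParameters:
    """Typical (population-mean) parameters conditioned on the covariates.

    Requires resolved covariates. Deterministic: applies the configured
    covariate relations to the typical CL, V and the VKORC1-specific EDK50.
    """
    if not cov.resolved:
        raise ValueError("covariates must be resolved first "
                         "(see resolve_missing_covariates)")
    rel = pop.covariate_relations
    try:
        cyp_cl = rel.cyp2c9_cl_mult[cov.cyp2c9]
        cyp_edk = rel.cyp2c9_edk50_mult.get(cov.cyp2c9, 1.0)
        edk50_base = pop.edk50_by_vkorc1[cov.vkorc1]
    except KeyError as exc:
        raise ConfigurationError(f"no coefficient for genotype {exc}") from exc

    wt_ratio = cov.weight / rel.ref_weight
    cl = (pop.tv_cl * wt_ratio ** rel.cl_weight_exp
          * math.exp(-rel.cl_age_slope * (cov.age - rel.ref_age)) * cyp_cl)
    v = pop.tv_v * wt_ratio ** rel.v_weight_exp
    edk50 = edk50_base * cyp_edk * wt_ratio ** rel.edk50_weight_exp
    return IndividualParameters(k10=cl / v, edk50=edk50)


def effect(dose_rate: float, pop: PopulationModel, indiv: IndividualParameters) -> float:
    """Sigmoid inhibition of coagulation-factor synthesis at a dose rate.

    EFF = E_max * DR^gamma / (EDK50^gamma + DR^gamma); zero at DR = 0,
    strictly increasing, saturating at E_max.
    """
    if dose_rate < 0:
        raise ValueError(f"dose rate must be >= 0, got {dose_rate}")
    if dose_rate == 0.0:
        return 0.0
    drg = dose_rate ** pop.gamma
    return pop.emax * drg / (indiv.edk50 ** pop.gamma + drg)


@dataclass
class ModelState:
    """Drug amount plus the six transit-compartment activities.

    Pre-treatment: ``a = 0`` and every activity 1 (full coagulation-factor
    activity), which is the stationary point of the untreated system.
    """

    a: float = 0.0
    c1: np.ndarray = field(default_factory=lambda: np.ones(3))
    c2: np.ndarray = field(default_factory=lambda: np.ones(3))

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.a], np.asarray(self.c1, float),
                               np.asarray(self.c2, float)))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, float)
        if y.shape != (7,):
            raise ValueError("state vector must have 7 components")
        return cls(a=float(y[0]), c1=y[1:4].copy(), c2=y[4:7].copy())


def state_derivative(
    state: ModelState,
    indiv: IndividualParameters,
    pop: PopulationModel,
    forced_eff: float | None = None,
) -> ModelState:
    """Time derivative of the full state.

    dA/dt = -k10*A; DR = k10*A drives the shared inhibition EFF; each chain
    is a three-compartment cascade with rate 3/MTT fed by (1 - EFF).
    ``forced_eff`` overrides the computed inhibition (used by solver
    verification against linear-cascade closed forms).
    """
    eff = effect(indiv.k10 * state.a, pop, indiv) if forced_eff is None else forced_eff
    k1 = 3.0 / pop.mtt1
    k2 = 3.0 / pop.mtt2
    inflow = 1.0 - eff
    c1, c2 = np.asarray(state.c1, float), np.asarray(state.c2, float)
    dc1 = k1 * np.array([inflow - c1[0], c1[0] - c1[1], c1[1] - c1[2]])
    dc2 = k2 * np.array([inflow - c2[0], c2[0] - c2[1], c2[1] - c2[2]])
    return ModelState(a=-indiv.k10 * state.a, c1=dc1, c2=dc2)


def inr_from_state(state: ModelState, baseline_inr: float, pop: PopulationModel) -> float:
    """Predicted INR: baseline + INR_max * (1 - (C1_3 + C2_3)/2)."""
    return baseline_inr + pop.inr_max * (1.0 - (state.c1[2] + state.c2[2]) / 2.0)
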