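import dataclasses

import pytest
from hypothesis import settings

from coumadose import io
from coumadose.model_core import (
    CovariateRelations,
    PatientCovariates,
    PopulationModel,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_pop() -> PopulationModel:
    return io.demo_population()


@pytest.fixture(scope="session")
def plain_pop() -> PopulationModel:
    """Covariate-free model: CL 0.2 L/h, V 10 L (k10 = 0.02/h), single EDK50."""
    return PopulationModel(
        tv_cl=0.2,
        tv_v=10.0,
        edk50_by_vkorc1={"G/G": 1.0, "A/G": 1.0, "A/A": 1.0},  # mg/h
        gamma=1.0,
        mtt1=10.0,
        mtt2=50.0,
        omega_k10=0.09,
        omega_edk50=0.09,
        sigma_add=0.1,
        covariate_relations=CovariateRelations(
            cl_weight_exp=0.0, v_weight_exp=0.0, cl_age_slope=0.0,
            edk50_weight_exp=0.0,
        ),
    )


@pytest.fixture(scope="session")
def small_noise_demo(demo_pop) -> PopulationModel:
    """Demo parameters with near-noise-free residual error (recovery arm)."""
    return dataclasses.replace(demo_pop, sigma_add=0.01)


@pytest.fixture
def adult_cov() -> PatientCovariates:
    return PatientCovariates(
        age=50.0, weight=70.0, cyp2c9="*1/*1", vkorc1="A/G",
        ethnicity="Caucasian", baseline_inr=1.0,
        target_low=2.0, target_high=3.0, dosing_interval=24.0,
    )


@pytest.fixture
def child_cov() -> PatientCovariates:
    return PatientCovariates(
        age=5.0, weight=20.0, cyp2c9="*2/*2", vkorc1="A/A",
        ethnicity="Caucasian", baseline_inr=1.2,
        target_low=2.0, target_high=3.0, dosing_interval=24.0,
    )
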