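import numpy as np
import pandas as pd
import pytest

from claimseg import fixtures
from claimseg.cohort_features import EncodingScheme, polar_encode
from claimseg.synthetic_claims import (
    ClusterDemographics,
    ClusterUtilization,
    CohortSpec,
    CostSpec,
    generate_cohort,
)


def uniform_demographics(age_mean=40.0, age_sd=10.0, p_female=0.5):
    return ClusterDemographics(
        age_mean, age_sd, p_female,
        {"TANF": 0.4, "SSI": 0.4, "Expansion": 0.1, "Medicare-eligible": 0.1},
        {"White": 0.4, "Black": 0.2, "Hispanic": 0.15, "Asian": 0.05,
         "Other": 0.05, "Missing": 0.15},
    )


def single_cluster_spec(n_patients, seed=0, ed_mean=4.0, prev_ed_mean=1.5,
                        adm_mean=0.5, prev_adm_mean=0.1, prevalence=None):
    """One-cluster cohort recipe for targeted distributional checks."""
    names = list(fixtures.CONDITION_NAMES)
    prev = prevalence if prevalence is not None else [0.3] * len(names)
    return CohortSpec(
        n_patients=n_patients,
        condition_names=names,
        mixing_weights=[1.0],
        condition_prevalence=[prev],
        demographics=[uniform_demographics()],
        utilization=[ClusterUtilization(adm_mean, 3.0, ed_mean,
                                        prev_adm_mean, prev_ed_mean)],
        cost=CostSpec(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def fixture6_cohort():
    """Moderate-size draw from the bundled six-cluster recipe."""
    return generate_cohort(fixtures.fixture6_spec(n_patients=2000, seed=42))


@pytest.fixture(scope="session")
def fixture6_features(fixture6_cohort):
    scheme = EncodingScheme.default(fixture6_cohort.spec.condition_names)
    return polar_encode(fixture6_cohort.patient_years, scheme)


@pytest.fixture
def tiny_patient_years():
    """Hand-built six-patient cohort for exact-arithmetic checks."""
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(1, 7)],
        "age": [30, 40, 50, 60, 25, 35],
        "female": [1, 0, 1, 1, 0, 1],
        "eligibility": ["TANF", "SSI", "TANF", "SSI", "Expansion", "TANF"],
        "race_ethnicity": ["White", "Black", "White", "Missing", "Hispanic", "White"],
        "cond_diabetes": [1, 0, 1, 1, 0, 0],
        "cond_asthma": [0, 0, 1, 0, 1, 1],
        "admissions": [0, 1, 2, 0, 0, 3],
        "hospital_days": [0, 2, 5, 0, 0, 9],
        "ed_visits": [1, 0, 4, 2, 0, 6],
        "preventable_admissions": [0, 1, 1, 0, 0, 2],
        "preventable_ed_visits": [1, 0, 2, 1, 0, 3],
        "annual_spend": [1000.0, 20000.0, 45000.0, 3000.0, 800.0, 90000.0],
    })
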