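import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stoprace.experiments import CohortSpec, calibrated_sigma
from stoprace.race import RaceParams, drift_from_latency

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def abcd_race_params() -> RaceParams:
    """Race parameters for the grand-mean subject (go RT 543, SSRT 282),
    with the diffusion coefficient calibrated to 90% go accuracy."""
    return RaceParams(
        mu_go=drift_from_latency(543.0),
        mu_stop=drift_from_latency(282.0),
        sigma=calibrated_sigma(CohortSpec()),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200508)


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    return dataclasses.replace(CohortSpec(), n_subjects=12, seed=7)
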