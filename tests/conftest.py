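import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import crmed
from crmed import datasets
from crmed.model import DoseOutcomeData, calibrate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return crmed.default_design()


@pytest.fixture(scope="session")
def prior():
    return crmed.default_prior()


@pytest.fixture(scope="session")
def lt32_trial(config):
    return datasets.lt32_history(config.grid)


@pytest.fixture(scope="session")
def lt32_rows():
    return datasets.lt32_posterior_rows()


@pytest.fixture(scope="session")
def cohort1_anchor(lt32_trial):
    """First-cohort data and printed posterior row: the calibration anchor."""
    r = lt32_trial.records[0]
    data = DoseOutcomeData.empty(5).add(r.dose_index, r.n, r.n_success)
    return data, datasets.lt32_posterior_rows()[0]


@pytest.fixture(scope="session")
def calibrated(cohort1_anchor, config):
    """Prior scale and estimator variant calibrated on the first-cohort anchor."""
    data, row1 = cohort1_anchor
    return calibrate(data, row1, config.skeleton)
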