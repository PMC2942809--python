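"""Shared fixtures: the calibrated model is expensive enough to build once."""

import logging

import pytest

from serotonin_terminal.calibration import (
    CalibrationTargets,
    baseline_model,
)

# the printed-constant infeasibility warning is expected and tested
# explicitly; keep it out of every other test's output
logging.getLogger("serotonin_terminal.calibration").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def targets():
    return CalibrationTargets()


@pytest.fixture(scope="session")
def model():
    """(params, baseline_state, autoreceptor_config) — calibrated."""
    return baseline_model()


@pytest.fixture(scope="session")
def params(model):
    return model[0]


@pytest.fixture(scope="session")
def baseline_state(model):
    return model[1]


@pytest.fixture(scope="session")
def autoreceptors(model):
    return model[2]
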