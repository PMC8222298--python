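"""Shared fixtures: one calibration and one reference estimator design per
session (calibration is deterministic, ~5 s)."""

from __future__ import annotations

import numpy as np
import pytest

from cpgwalk.controller import calibrate_nominal
from cpgwalk.engine import SimSystem
from cpgwalk.estimator import design_estimator
from cpgwalk.noise import NoiseSpec
from cpgwalk.walker import WalkerParams


@pytest.fixture(scope="session")
def params():
    return WalkerParams()


@pytest.fixture(scope="session")
def calibrated(params):
    control, gait = calibrate_nominal(params)
    return control, gait


@pytest.fixture(scope="session")
def control(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def gait(calibrated):
    return calibrated[1]


@pytest.fixture(scope="session")
def ref_noise():
    return NoiseSpec()


@pytest.fixture(scope="session")
def design(params, control, ref_noise):
    return design_estimator(params, control, ref_noise)


@pytest.fixture(scope="session")
def system(params, control, gait, design):
    return SimSystem(params, control, gait, design.L)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
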