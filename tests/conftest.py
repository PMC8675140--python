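"""Shared fixtures: the heavier end-to-end example runs are computed once
per session and reused by the acceptance checks."""

import warnings

import numpy as np
import pytest

from icwflab.experiments import run_example


def pytest_configure(config):
    # overlap rank deficiency is expected for redundant stochastic bases;
    # keep the reports but don't fail anything on it
    warnings.filterwarnings("default", message="overlap rank deficient")


@pytest.fixture(scope="session")
def bopes_run():
    return run_example("bopes_h2")


@pytest.fixture(scope="session")
def kick_run():
    return run_example("kick_h2")


@pytest.fixture(scope="session")
def scattering_run():
    return run_example("scattering")


@pytest.fixture(scope="session")
def shin_metiu_run():
    return run_example("shin_metiu")


@pytest.fixture(scope="session")
def conical_run():
    return run_example("conical")
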