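"""Shared fixtures.

The calibrated drug is expensive (~10 s) and deterministic, so it is
computed once per session and shared by the validation, dose-finding and
acceptance tests.
"""

from __future__ import annotations

import warnings

import pytest

from pedpk.calibration import (
    ADULT_REFERENCE_AGE,
    calibrate_workflow,
    load_observations,
)
from pedpk.drug import DrugParameters, Formulation
from pedpk.physiology import build_individual


@pytest.fixture(scope="session")
def reference_observations():
    return load_observations()


@pytest.fixture(scope="session")
def calibration(reference_observations):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate_workflow(reference_observations)


@pytest.fixture(scope="session")
def calibrated_drug(calibration) -> DrugParameters:
    return calibration.drug


@pytest.fixture(scope="session")
def adult() -> "Individual":
    return build_individual(ADULT_REFERENCE_AGE, "male")


@pytest.fixture()
def formulation() -> Formulation:
    return Formulation()
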