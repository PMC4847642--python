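"""Shared fixtures.

Fitted estimators are expensive, so fits that several tests inspect are
session-scoped and reused.
"""

import warnings

import numpy as np
import pytest

from polyhazard.estimators import PolyhazardExtrapolator
from polyhazard.simulation import generate_scenario_data, get_scenario


@pytest.fixture(scope="session")
def m2_pair():
    """One (population, study) dataset pair from the ICD-like scenario."""
    return generate_scenario_data(get_scenario("model2_b15"), seed=11)


@pytest.fixture(scope="session")
def pw_treatment_fit(m2_pair):
    """Poly-Weibull joint fit with a treatment-effect prior attached.

    The treated arm contributes no individual data, so its log hazard
    ratio gamma is informed by the prior alone (hazard ratio 0.50,
    prior sd 0.148 on the log scale).
    """
    pop, study = m2_pair
    est = PolyhazardExtrapolator(
        treatment_hazard_ratio=0.5, treatment_sd=0.148, random_state=5
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(pop.concat(study))
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
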