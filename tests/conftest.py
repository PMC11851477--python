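"""Shared fixtures for the test suite.

The expensive known-circuit recovery experiment (20 particles x 500
iterations x 5 seeds) is session-scoped so the acceptance check and the
budget-monotonicity property share one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capfit import CircuitParams, assemble_state_space, load_patients, to_transfer_function
from capfit.validation import recovery_experiment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Reference fitted circuit constants reported for the capillary model.
REFERENCE_FIT = dict(r1=89.784, r2=426.55, l=27.506, c=0.00040675)

#: Seeds for the stochastic optimizer experiments, fixed once.
RECOVERY_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def reference_params() -> CircuitParams:
    return CircuitParams(**REFERENCE_FIT)


@pytest.fixture(scope="session")
def reference_tf(reference_params):
    return to_transfer_function(assemble_state_space(reference_params))


@pytest.fixture(scope="session")
def patients():
    return {p.patient_id: p for p in load_patients()}


@pytest.fixture(scope="session")
def recovery_500():
    """Full-budget recovery experiment on the known (1, 0.5, 0.25) circuit."""
    return recovery_experiment(seeds=RECOVERY_SEEDS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
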