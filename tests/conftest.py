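"""Shared fixtures: one moderately sized simulated dataset reused across tests."""

import pytest
from hypothesis import HealthCheck, settings

from smfret.classify import ThresholdClassificationModel
from smfret.kinetics import KineticsModel, init_from_classification
from smfret.qc import run_qc
from smfret.simulate import generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """250 trajectories at the default study conditions (no contaminants)."""
    return generate_dataset(250, rng_seed=42)


@pytest.fixture(scope="session")
def qc_result(default_dataset):
    return run_qc(default_dataset)


@pytest.fixture(scope="session")
def classification(qc_result):
    return ThresholdClassificationModel(qc_result.retained).fit(rng_seed=7)


@pytest.fixture(scope="session")
def kinetics_results(qc_result, classification):
    init = init_from_classification(classification, jitter_seed=3)
    return KineticsModel(qc_result.retained, init=init).fit()


@pytest.fixture(scope="session")
def decoded_frames(kinetics_results, qc_result):
    return kinetics_results.decoded_frame(qc_result.retained)
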