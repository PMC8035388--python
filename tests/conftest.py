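"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import pytest

from workloadcv import OperatorPolicy, TaskConfig, WorkloadModel, simulate_study
from workloadcv.pipeline import study_feature_table


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """Shortened blocks (60 s, 6 per session) for fast end-to-end tests."""
    return TaskConfig(block_duration=60.0, n_blocks=6)


@pytest.fixture(scope="session")
def tiny_study(small_config):
    """Six participants x two days under the default generative effects."""
    return simulate_study(
        6, config=small_config, policy=OperatorPolicy(), model=WorkloadModel(), seed=11
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_study):
    return study_feature_table(tiny_study)


@pytest.fixture(scope="session")
def null_model() -> WorkloadModel:
    return WorkloadModel().null_effects()


@pytest.fixture()
def rng_seed() -> int:
    return 20240917
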