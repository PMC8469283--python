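"""Shared fixtures: small deterministic synthetic configurations."""

import numpy as np
import pytest

from cortemg.synthetic import GeneratorConfig, simulate_session


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Smallest config that exercises every stage: 4 sessions around a
    lesion, 4 units, 2 muscles, 40 s per session."""
    return GeneratorConfig(
        seed=42, n_sessions=4, lesion_session=2, session_duration=40.0,
        n_units_initial=4, unit_dropout_rate=0.0, muscles=("LS", "RS"),
        walk_fraction_post=(0.3, 0.6), steps_per_run_post=(10.0, 30.0))


@pytest.fixture(scope="session")
def tiny_pre_session(tiny_config):
    return simulate_session(tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_post_session(tiny_config):
    return simulate_session(tiny_config, 2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
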