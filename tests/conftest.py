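"""Shared fixtures: synthetic patients sized for fast, deterministic tests."""

import numpy as np
import pytest

from preictal import RunConfig, SynthConfig, generate_feature_dataset


@pytest.fixture(scope="session")
def signal_patient_cfg() -> SynthConfig:
    """A small signal-level patient: minutes of data, one seizure."""
    return SynthConfig(
        n_seizures=1,
        interictal_gap_hours=0.5,
        lead_in_hours=0.4,
        tail_hours=0.05,
        preictal_minutes=10.0,
        n_channels=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def feature_patient():
    """A default-conditions feature-level patient with a clear signature."""
    fm, seizures = generate_feature_dataset(SynthConfig(effect_size=3.0, seed=5))
    return fm, seizures


@pytest.fixture(scope="session")
def small_feature_cfg() -> SynthConfig:
    """A compact feature-level patient for ensemble-backend tests."""
    return SynthConfig(
        interictal_gap_hours=1.2,
        lead_in_hours=1.0,
        tail_hours=0.25,
        effect_size=2.0,
        n_features=12,
        signature_features=("Ch1:rel_power_alpha", "Ch1:rel_power_beta"),
        seed=3,
    )


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=17)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
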