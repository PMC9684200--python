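import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from semgdeco.dataset import MotionLabel, chronological_split, slice_windows
from semgdeco.features import FeatureSpec, extract_dataset
from semgdeco.preprocessing import preprocess_trial
from semgdeco.synthetic import (
    ActivationModel,
    SyntheticConfig,
    default_activation_model,
    simulate_subject_dataset,
    simulate_trial,
)


@pytest.fixture(scope="session")
def model() -> ActivationModel:
    return default_activation_model()


@pytest.fixture(scope="session")
def short_config() -> SyntheticConfig:
    """Short trials for fast tests: 3 s at 1000 Hz -> 20 windows/mode."""
    return SyntheticConfig(trial_duration=3.0, seed=7)


@pytest.fixture(scope="session")
def short_trial(model, short_config):
    return simulate_trial(short_config, model, MotionLabel(1, 2, 1), "S1", seed=7)


@pytest.fixture(scope="session")
def small_feature_table(model, short_config):
    """Features of one synthetic subject at the short-trial scale."""
    recs = simulate_subject_dataset(short_config, model, "S1", seed=7)
    recs = [preprocess_trial(r) for r in recs]
    windows = [w for r in recs for w in slice_windows(r)]
    split = chronological_split(windows, 0.9, shuffle_seed=7)
    return extract_dataset(split, FeatureSpec())
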