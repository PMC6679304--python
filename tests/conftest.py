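import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgrt
from emgrt.ann import TrainConfig
from emgrt.evaluate import train_pipeline
from emgrt.features import WindowSpec
from emgrt.preprocess import FilterSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_config() -> emgrt.SynthConfig:
    """Small 3-gesture generator configuration for fast pipeline tests."""
    return emgrt.SynthConfig(n_gestures=3, burst_duration_s=0.5,
                             onset_delay_s=(0.05, 0.15), seed=7)


@pytest.fixture(scope="session")
def tiny_window_spec() -> WindowSpec:
    return WindowSpec(length_samples=20, stride_samples=1)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    train, test = emgrt.generate_dataset(tiny_config, 3, 3,
                                         train_duration_s=1.5,
                                         test_duration_s=2.0,
                                         rest_reps_train=3)
    return train, test


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_window_spec):
    """Classifier trained on the small synthetic session (4 classes:
    rest + 3 gestures); detection frames shortened to match the small
    window."""
    train_recs, _ = tiny_dataset
    tc = TrainConfig(learning_rate=0.5, max_epochs=250, seed=3,
                     tolerance=1e-8)
    return train_pipeline(train_recs, FilterSpec(), tiny_window_spec, tc,
                          n_classes=4, frame_len=16)
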