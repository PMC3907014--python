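import numpy as np
import pytest

from gaitbci.online_decoder import calibrate_thresholds, run_online_session
from gaitbci.prediction_model import ModelConfig, train_model
from gaitbci.synthetic_data import (
    SynthConfig,
    generate_online_session,
    generate_training_session,
)


@pytest.fixture(scope="session")
def strong_cfg():
    return SynthConfig(seed=1, effect_size=3.0, reaction_delay=0.0)


@pytest.fixture(scope="session")
def strong_training(strong_cfg):
    """600-s training session with strong (d'=3) modulation."""
    return generate_training_session(strong_cfg)


@pytest.fixture(scope="session")
def strong_model(strong_training):
    rec, cues = strong_training
    return train_model(rec, cues, ModelConfig(seed=11))


@pytest.fixture(scope="session")
def strong_thresholds(strong_training, strong_model):
    """Thresholds calibrated by replaying the training session online."""
    rec, cues = strong_training
    post, _ = run_online_session(rec, strong_model, 0.5, 0.5, cues)
    labels = np.array(
        [cues.label_at(t - 0.375) or "IDLE" for t in post.times]
    )
    cal = calibrate_thresholds(post.P_bar, labels)
    return cal.t_i, cal.t_w


@pytest.fixture(scope="session")
def strong_online(strong_cfg):
    return generate_online_session(strong_cfg)


@pytest.fixture(scope="session")
def chance_training():
    """600-s training session with no class modulation (d'=0)."""
    return generate_training_session(SynthConfig(seed=5, effect_size=0.0))


@pytest.fixture(scope="session")
def d2_training():
    """Training session at the calibrated d'=2 effect size."""
    return generate_training_session(SynthConfig(seed=3, effect_size=2.0))
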