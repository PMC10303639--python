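import numpy as np
import pytest

from mobileqrs import SyntheticConfig, generate_session, PipelineConfig
from mobileqrs.pipeline import run_training


@pytest.fixture(scope="session")
def small_session():
    """A 3-trial synthetic subject with default noise/artifact settings."""
    cfg = SyntheticConfig(n_trials=3, seed=11)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_model(small_session):
    s = small_session
    cfg = s.config
    pc = PipelineConfig(fs=cfg.fs, seed=11)
    return run_training(
        s.train_mobile, s.train_chest_truth.annotation_track(), pc,
        cfg.evaluation_minutes(),
        template_ref=s.train_mobile_truth.annotation_track())


@pytest.fixture(scope="session")
def artifact_free_session():
    """Default broadband noise, but no motion-artifact bursts and no false
    spikes."""
    cfg = SyntheticConfig(n_trials=3, seed=11, artifact_gain=0.0,
                          artifact_burst_s=0.0, false_spike_rate=0.0)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free deterministic subject: no additive noise, no artifacts,
    no false spikes, constant heart rate and QRS duration."""
    cfg = SyntheticConfig(
        n_trials=2, seed=5, hr_drift_bpm=0.0, rr_jitter_ms=0.0,
        qrs_duration_sd_ms=0.0, qrs_drift_ms=0.0, chest_noise_sd=0.0,
        mobile_noise_sd=0.0, baseline_wander_amp=0.0, artifact_gain=0.0,
        artifact_burst_s=0.0, false_spike_rate=0.0)
    return generate_session(cfg)
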