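import numpy as np
import pytest

from eegdfc import EEGRecording, PipelineConfig, SubjectSpec


#: Scale used for Monte-Carlo cohort studies: small enough for replicated
#: cohorts, large enough (3000 samples, 66 pairs) for stable cumulants.
MC_CHANNELS = 12
MC_FS = 250.0
MC_DURATION = 12.0


def mc_subject_spec(**overrides) -> SubjectSpec:
    base = dict(n_channels=MC_CHANNELS, fs=MC_FS, duration=MC_DURATION)
    base.update(overrides)
    return SubjectSpec(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 4-second broadband noise recording at 250 Hz."""
    return EEGRecording(rng.standard_normal((4, 1000)), fs=250.0,
                        subject_id="S01", group="HC")


@pytest.fixture
def default_config():
    return PipelineConfig()


def tone(freq: float, fs: float, n: int, amplitude: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)
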