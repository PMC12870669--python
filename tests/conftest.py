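import numpy as np
import pytest

import sefpredict as sp


@pytest.fixture(scope="session")
def bursty_recording():
    """One 8-channel recording with beta bursts on every channel (default
    calibrated amplitude, so planted events sit near peak FOM ~10)."""
    bursts = {
        ch: [sp.BurstSpec("beta", 20.0, 1.5, 10.0, 8.0)]
        for ch in sp.FRONTAL_CHANNELS
    }
    spec = sp.RecordingSpec(duration_s=60.0, fs_hz=200.0, seed=11, bursts=bursts)
    rec, planted = sp.generate_recording(spec)
    return rec, planted


@pytest.fixture(scope="session")
def bursty_epochs(bursty_recording):
    rec, _ = bursty_recording
    epochs, _ = sp.preprocess(rec)
    return epochs


@pytest.fixture(scope="session")
def feature_cohort():
    """Feature-level sertraline-like cohort (n=82): SEF table, clinical,
    ground truth."""
    cspec = sp.CohortSpec.sertraline_like(n_subjects=82, seed=7)
    return sp.generate_feature_cohort(cspec)


def make_sine_recording(freq_hz, fs=250.0, duration=30.0, n_channels=3,
                        amplitude=10.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    labels = [f"Ch{i}" for i in range(n_channels)]
    return sp.RawRecording(data=data, fs_hz=fs, channel_labels=labels, subject_id="sine")
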