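import numpy as np
import pytest

from oscishift import EpochSet


def make_tone_epochs(freq=20.0, fs=250.0, duration=2.0, n_trials=1, n_channels=1,
                     amplitude=1.0, phase=0.0):
    t = np.arange(int(round(fs * duration))) / fs
    tone = amplitude * np.cos(2 * np.pi * freq * t + phase)
    data = np.broadcast_to(tone, (n_trials, n_channels, t.size)).copy()
    return EpochSet(
        data=data,
        fs=fs,
        time=t,
        channel_ids=[f"ch{i:02d}" for i in range(n_channels)],
        trial_condition=np.asarray(["A"] * n_trials),
        trial_correct=np.ones(n_trials, dtype=bool),
    )


@pytest.fixture
def tone_epochs():
    return make_tone_epochs()


@pytest.fixture
def small_epochs():
    rng = np.random.default_rng(42)
    n_trials, n_channels, n_samples = 4, 2, 500
    fs = 250.0
    return EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        fs=fs,
        time=np.arange(n_samples) / fs,
        channel_ids=["L_dlPFC", "L_vmPFC"],
        trial_condition=np.asarray(["A", "A", "B", "B"]),
        trial_correct=np.asarray([True, True, True, False]),
        subject_id="sub01",
    )
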