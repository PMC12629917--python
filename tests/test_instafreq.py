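"""Instantaneous-frequency estimation: tones, chirps, AM immunity,
median-cascade bounds, condition contrasts."""

import numpy as np
import pytest

from oscishift import (
    BandSpec,
    EpochSet,
    SimConfig,
    bandpass,
    instantaneous_frequency,
    simulate_subject,
    subject_condition_if,
)
from oscishift.instafreq import median_filter_rows, median_kernels
from scipy import ndimage
from tests.conftest import make_tone_epochs

BETA = BandSpec(13.0, 35.0)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        e = make_tone_epochs(freq=20.0)
        out = bandpass(e, BETA)
        mid = slice(150, 350)
        ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(e.data[0, 0, mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_stopband_tone_suppressed(self):
        e = make_tone_epochs(freq=5.0)
        out = bandpass(e, BETA)
        mid = slice(150, 350)
        assert np.abs(out.data[0, 0, mid]).max() < 0.01

    def test_idempotent_in_passband(self):
        e = make_tone_epochs(freq=24.0)
        once = bandpass(e, BETA)
        twice = bandpass(once, BETA)
        mid = slice(150, 350)
        ratio = np.abs(twice.data[0, 0, mid]).max() / np.abs(once.data[0, 0, mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_too_short_epoch_reports_minimum(self):
        e = make_tone_epochs(duration=0.2)
        with pytest.raises(ValueError, match="needs >="):
            bandpass(e, BETA)


class TestMedianFilterCascade:
    def test_matches_ndimage_reference(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((7, 200))
        for k in (3, 25, 101):
            mine = median_filter_rows(x, k)
            ref = ndimage.median_filter(x, size=(1, k), mode="nearest")
            assert np.array_equal(mine, ref)

    def test_kernels_are_odd_and_span_range(self):
        ks = median_kernels(250.0, 10, (10.0, 400.0))
        assert len(ks) == 10
        assert all(k % 2 == 1 for k in ks)
        assert ks[0] == 3 and ks[-1] == 101

    def test_output_bounded_by_raw_extremes(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 300))
        for k in (5, 51):
            y = median_filter_rows(x, k)
            assert y.min() >= x.min() and y.max() <= x.max()


class TestInstantaneousFrequency:
    def test_pure_tone_recovery(self):
        e = make_tone_epochs(freq=20.0, fs=250.0, duration=2.0)
        ifs = instantaneous_frequency(e)
        v = ifs.ifreq[0, 0][ifs.valid_mask[0, 0]]
        assert np.abs(v - 20.0).mean() < 0.05

    def test_linear_chirp_midpoint(self):
        fs, T = 250.0, 2.0
        t = np.arange(int(fs * T)) / fs
        chirp = np.cos(2 * np.pi * (16.0 * t + (24.0 - 16.0) / (2 * T) * t ** 2))
        e = EpochSet(data=chirp[None, None, :], fs=fs, time=t, channel_ids=["c"],
                     trial_condition=np.asarray(["A"]),
                     trial_correct=np.ones(1, dtype=bool))
        ifs = instantaneous_frequency(e)
        mid = int(fs * T / 2)
        assert ifs.valid_mask[0, 0, mid]
        assert ifs.ifreq[0, 0, mid] == pytest.approx(20.0, abs=0.2)

    def test_amplitude_modulation_not_frequency_modulation(self):
        # Hann-enveloped 18 Hz tone: IF stays at 18 inside the envelope's top half
        fs, n = 250.0, 500
        t = np.arange(n) / fs
        env = np.hanning(n)
        x = env * np.cos(2 * np.pi * 18.0 * t)
        e = EpochSet(data=x[None, None, :], fs=fs, time=t, channel_ids=["c"],
                     trial_condition=np.asarray(["A"]),
                     trial_correct=np.ones(1, dtype=bool))
        ifs = instantaneous_frequency(e)
        top = (env >= 0.5) & ifs.valid_mask[0, 0]
        assert np.all(np.abs(ifs.ifreq[0, 0, top] - 18.0) < 0.2)

    def test_valid_mask_excludes_edges(self):
        e = make_tone_epochs(freq=20.0)
        ifs = instantaneous_frequency(e)
        assert not ifs.valid_mask[0, 0, 0]
        assert not ifs.valid_mask[0, 0, -1]
        assert ifs.valid_mask[0, 0].any()

    def test_condition_shift_recovery(self):
        cfg = SimConfig(osc_mode="sustained", delta_f=0.3, osc_amplitude=8.0,
                        freq_jitter_sd=0.1, n_trials_per_condition=60)
        dec, _, _ = simulate_subject(cfg, 1, seed=21)
        s = subject_condition_if(instantaneous_frequency(dec))
        eff = [dec.channel_index(c) for c in cfg.effect_channels]
        assert s["signed_diff"][eff].mean() == pytest.approx(0.30, abs=0.05)


class TestSubjectConditionIF:
    def _ifs(self, seed=0, delta=0.0):
        cfg = SimConfig(osc_mode="sustained", delta_f=delta, n_trials_per_condition=20)
        dec, _, _ = simulate_subject(cfg, 1, seed=seed)
        return dec, instantaneous_frequency(dec)

    def test_label_swap_negates_difference(self):
        dec, ifs = self._ifs(seed=3, delta=0.4)
        s1 = subject_condition_if(ifs)
        swapped = ifs
        swapped.trial_condition = np.where(ifs.trial_condition == "A", "B", "A")
        s2 = subject_condition_if(swapped)
        assert np.allclose(s1["diff"], -s2["diff"], equal_nan=True)

    def test_empty_condition_after_filter_raises(self):
        dec, ifs = self._ifs(seed=4)
        ifs.trial_correct = ifs.trial_condition == "A"  # all B trials incorrect
        with pytest.raises(ValueError, match="'B'"):
            subject_condition_if(ifs, correct_only=True)

    def test_identical_trials_give_that_trial_back(self):
        e = make_tone_epochs(freq=20.0, n_trials=4)
        e.trial_condition = np.asarray(["A", "A", "B", "B"])
        ifs = instantaneous_frequency(e)
        s = subject_condition_if(ifs)
        assert np.allclose(s["mean_if"][0][:, s["valid_mask"][0]],
                           s["mean_if"][1][:, s["valid_mask"][0]])
        assert np.nanmax(np.abs(s["diff"])) < 1e-9
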