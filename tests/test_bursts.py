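"""Morlet TFR and spectral-event detection, summaries and contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

from oscishift import (
    BandSpec,
    BurstSummary,
    SimConfig,
    burst_contrasts,
    detect_spectral_events,
    make_fractal_noise,
    morlet_tfr,
    summarize_bursts,
)
from tests.conftest import make_tone_epochs

BETA = BandSpec(13.0, 35.0)


def _burst_epochs(n_trials=20, fs=250.0, n=500, noise_amp=1.0, burst_amp=6.0,
                  freq=20.0, center=0.8, cycles=7, seed=3):
    """1/f background with one strong Hann burst per trial at a known spot."""
    e = make_fractal_noise(n_trials, 1, n, fs, 1.0, amplitude=noise_amp, seed=seed)
    t = e.time
    dur = cycles / freq
    i0 = int((center - dur / 2) * fs)
    n_ev = int(dur * fs)
    env = np.hanning(n_ev)
    data = e.data.astype(np.float64)
    data[:, 0, i0:i0 + n_ev] += burst_amp * env * np.cos(
        2 * np.pi * freq * (t[i0:i0 + n_ev] - center))
    e.data = data
    return e


class TestMorletTFR:
    def test_zero_signal_zero_power(self):
        e = make_tone_epochs(n_trials=2)
        e.data = np.zeros_like(e.data)
        tfr = morlet_tfr(e)
        assert np.all(tfr.power == 0)

    def test_tone_localized_at_grid_bin(self):
        e = make_tone_epochs(freq=20.0)
        tfr = morlet_tfr(e)
        interior = tfr.edge_mask()
        fi = np.argmax(tfr.power[0, 0], axis=0)
        cols = interior.all(axis=0)
        assert np.all(tfr.freqs[fi[cols]] == pytest.approx(20.0, abs=1.0))

    def test_burst_fwhm_matches_direct_convolution(self):
        # oracle: numeric FWHM of |morlet * burst|^2 computed by direct convolution
        fs, freq, cycles = 250.0, 20.0, 7
        dur = cycles / freq
        n_ev = int(dur * fs)
        tt = (np.arange(n_ev) - n_ev / 2) / fs
        burst = np.hanning(n_ev) * np.cos(2 * np.pi * freq * np.arange(n_ev) / fs)
        sigma_t = cycles / (2 * np.pi * freq)
        wt = np.arange(-4 * sigma_t, 4 * sigma_t, 1 / fs)
        wavelet = np.exp(2j * np.pi * freq * wt) * np.exp(-wt ** 2 / (2 * sigma_t ** 2))
        resp = np.abs(np.convolve(burst, wavelet, mode="same")) ** 2
        half = resp >= resp.max() / 2
        oracle_fwhm = half.sum() / fs

        e = _burst_epochs(n_trials=1, noise_amp=0.0, burst_amp=1.0, seed=0)
        tfr = morlet_tfr(e)
        fi = int(np.argmin(np.abs(tfr.freqs - freq)))
        row = tfr.power[0, 0, fi]
        meas = (row >= row.max() / 2).sum() / fs
        assert meas == pytest.approx(oracle_fwhm, rel=0.3)

    def test_grid_outside_nyquist_rejected(self):
        e = make_tone_epochs()
        with pytest.raises(ValueError):
            morlet_tfr(e, freqs=np.asarray([200.0]))


class TestDetectSpectralEvents:
    def test_zero_signal_zero_events(self):
        e = make_tone_epochs(n_trials=2)
        e.data = np.zeros_like(e.data)
        assert detect_spectral_events(morlet_tfr(e), fom_threshold=6.0) == []

    def test_single_burst_recovered(self):
        e = _burst_epochs(n_trials=20, burst_amp=6.0)
        tfr = morlet_tfr(e)
        # threshold high enough that chi^2 background fluctuations stay below
        events = detect_spectral_events(tfr, band=BETA, fom_threshold=12.0)
        per_trial = {}
        for ev in events:
            per_trial.setdefault(ev.trial, []).append(ev)
        recovered = 0
        for tr in range(20):
            hits = [ev for ev in per_trial.get(tr, [])
                    if abs(ev.peak_freq - 20.0) <= 1.0 and abs(ev.peak_time - 0.8) <= 0.05]
            recovered += bool(hits)
        assert recovered >= 18
        assert len(events) <= 20 + 4  # few spurious background events

    def test_threshold_monotonicity(self):
        e = _burst_epochs(n_trials=10, burst_amp=4.0)
        tfr = morlet_tfr(e)
        counts = [len(detect_spectral_events(tfr, band=BETA, fom_threshold=th))
                  for th in (2.0, 4.0, 6.0, 9.0, 14.0, 25.0)]
        assert counts == sorted(counts, reverse=True)

    def test_amplitude_rescaling_invariance(self):
        e = _burst_epochs(n_trials=5, burst_amp=6.0)
        tfr1 = morlet_tfr(e)
        e2 = e.copy()
        e2.data = e2.data * 37.5
        tfr2 = morlet_tfr(e2)
        ev1 = detect_spectral_events(tfr1, band=BETA, fom_threshold=8.0)
        ev2 = detect_spectral_events(tfr2, band=BETA, fom_threshold=8.0)
        assert [(e.trial, e.peak_time, e.peak_freq) for e in ev1] == [
            (e.trial, e.peak_time, e.peak_freq) for e in ev2]


class TestSummaries:
    def test_rate_arithmetic(self):
        e = _burst_epochs(n_trials=4, burst_amp=8.0)
        tfr = morlet_tfr(e)
        events = detect_spectral_events(tfr, band=BETA, fom_threshold=12.0)
        summ = summarize_bursts(events, e.trial_condition, window_len=2.0)
        total = sum(s.n_events for s in summ)
        assert total == len(events)
        for s in summ:
            assert s.mean_rate == pytest.approx(s.n_events / s.n_trials)
            assert s.rate_per_s == pytest.approx(s.mean_rate / 2.0)

    def test_poisson_rate_recovery_sparse_regime(self):
        # sparse, short bursts: detected rate within 3 SE of the Poisson mean
        # (dense regimes merge overlapping events and undercount by design)
        from oscishift import simulate_subject

        cfg = SimConfig(osc_mode="bursts", burst_rate=0.5, burst_len_cycles=3.0,
                        osc_amplitude=8.0, fractal_amplitude=0.5,
                        n_trials_per_condition=40, freq_jitter_sd=0.5)
        dec, _, log = simulate_subject(cfg, 1, seed=13)
        tfr = morlet_tfr(dec)
        events = detect_spectral_events(tfr, band=BETA, fom_threshold=12.0)
        summ = summarize_bursts(events, dec.trial_condition, window_len=1.5,
                                channel="L_dlPFC")
        lam = 0.5 * 1.5
        for s in summ:
            se = np.sqrt(lam / s.n_trials)
            assert abs(s.mean_rate - lam) < 3 * se

    def test_empty_condition_flagged(self):
        summ = summarize_bursts([], np.asarray(["A", "B"]), window_len=1.5)
        assert all(s.n_events == 0 and not s.defined for s in summ)


class TestBurstContrasts:
    @staticmethod
    def _pair(sid, fa, fb, ra=2.0, rb=2.0):
        return [
            BurstSummary(sid, "A", 10, 20, ra, ra / 1.5, fa),
            BurstSummary(sid, "B", 10, 20, rb, rb / 1.5, fb),
        ]

    def test_null_frequency_difference(self):
        pairs = [self._pair(f"s{i}", 20.0, 20.0) for i in range(5)]
        res = burst_contrasts(pairs)
        assert res["freq_contrast"]["t"] == 0.0
        assert res["freq_contrast"]["p"] == 1.0

    def test_closed_form_t(self):
        pairs = [self._pair("s1", 20.0, 21.0), self._pair("s2", 20.0, 22.0),
                 self._pair("s3", 20.0, 23.0)]
        res = burst_contrasts(pairs)
        assert res["freq_contrast"]["t"] == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res["freq_contrast"]["df"] == 2

    def test_rate_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        pairs = [self._pair(f"s{i}", 20.0, 20.5, ra=2.9 + rng.normal(0, 0.05),
                            rb=3.0 + rng.normal(0, 0.05)) for i in range(24)]
        res = burst_contrasts(pairs)
        for cond in ("A", "B"):
            assert res["rate_vs_zero"][cond]["p"] < 1e-6

    def test_undefined_subject_excluded_pairwise(self):
        pairs = [self._pair(f"s{i}", 20.0, 21.0) for i in range(4)]
        pairs.append(self._pair("s5", np.nan, 21.0))
        res = burst_contrasts(pairs)
        assert res["n_excluded"] == 1
        assert res["freq_contrast"]["df"] == 3
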