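"""Transient oscillatory event ("burst") detection and summaries.

Power is computed by complex Morlet wavelet convolution (7 cycles by
default) on a 1-Hz grid across the band of interest, normalized per
frequency by the median across all trials and times of a subject
("factors of median", FOM).  Suprathreshold regions in the (frequency,
time) plane are each reduced to a single event at the region's global
maximum; events are summarized per subject and condition as rates per
decision window and mean peak frequencies, with paired t contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sps

from .core import BandSpec, EpochSet

__all__ = [
    "TFR",
    "BurstEvent",
    "BurstSummary",
    "morlet_tfr",
    "detect_spectral_events",
    "summarize_bursts",
    "burst_contrasts",
]


@dataclass
class TFR:
    """Time-frequency power per (trial, channel, frequency, time)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float
    fs: float
    channel_ids: list
    trial_condition: np.ndarray
    subject_id: str = "s00"

    def edge_mask(self) -> np.ndarray:
        """(n_freqs, n_times) True where a full wavelet half-length fits."""
        half = self.n_cycles / (2.0 * self.freqs)  # seconds per frequency
        t0, t1 = self.times[0], self.times[-1]
        return (self.times[None, :] >= t0 + half[:, None]) & (
            self.times[None, :] <= t1 - half[:, None]
        )


@dataclass
class BurstEvent:
    trial: int
    channel: str
    peak_time: float
    peak_freq: float
    peak_power_fom: float
    duration: float  # FWHM in time at the peak frequency, s
    freq_span: float  # FWHM in frequency at the peak time, Hz


@dataclass
class BurstSummary:
    """Per (subject, condition) burst statistics."""

    subject_id: str
    condition: str
    n_trials: int
    n_events: int
    mean_rate: float  # events per window
    rate_per_s: float
    mean_peak_freq: float  # NaN when the condition has no events

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean_peak_freq)


def morlet_tfr(epochs: EpochSet, freqs=None, n_cycles: float = 7.0) -> TFR:
    """Complex Morlet wavelet power of every trial and channel.

    ``freqs`` defaults to 13–35 Hz in 1 Hz steps.  Requires the slowest
    wavelet (``n_cycles / min(freqs)`` seconds) to fit inside the window.
    """
    freqs = np.arange(13.0, 36.0) if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.min() <= 0 or freqs.max() >= epochs.fs / 2:
        raise ValueError("morlet_tfr: frequency grid outside (0, fs/2)")
    T = epochs.n_samples / epochs.fs
    if freqs.min() < n_cycles / T:
        raise ValueError(
            f"morlet_tfr: lowest frequency {freqs.min()} Hz needs a wavelet longer "
            f"than the {T} s window ({n_cycles} cycles)"
        )
    from mne.time_frequency import tfr_array_morlet

    power = tfr_array_morlet(
        epochs.data.astype(np.float64), sfreq=epochs.fs, freqs=freqs,
        n_cycles=n_cycles, output="power", zero_mean=True, verbose="error",
    )
    return TFR(
        power=power,
        freqs=freqs,
        times=epochs.time.copy(),
        n_cycles=n_cycles,
        fs=epochs.fs,
        channel_ids=list(epochs.channel_ids),
        trial_condition=epochs.trial_condition.copy(),
        subject_id=epochs.subject_id,
    )


def _fwhm(x: np.ndarray, grid: np.ndarray, peak_idx: int) -> float:
    """Full width at half maximum around ``peak_idx``, linearly interpolated."""
    half = x[peak_idx] / 2.0
    lo = grid[0]
    for i in range(peak_idx, 0, -1):
        if x[i - 1] < half:
            frac = (x[i] - half) / (x[i] - x[i - 1])
            lo = grid[i] - frac * (grid[i] - grid[i - 1])
            break
    hi = grid[-1]
    for i in range(peak_idx, len(x) - 1):
        if x[i + 1] < half:
            frac = (x[i] - half) / (x[i] - x[i + 1])
            hi = grid[i] + frac * (grid[i + 1] - grid[i])
            break
    return float(hi - lo)


def detect_spectral_events(tfr: TFR, band: BandSpec | None = None,
                           fom_threshold: float = 6.0) -> list[BurstEvent]:
    """Find suprathreshold time-frequency events per trial and channel.

    Power is normalized per (channel, frequency) by the median over all
    trials and times; 8-connected suprathreshold regions each contribute one
    event at their global maximum (ties broken toward earliest time, then
    lowest frequency), kept when the peak frequency lies inside ``band``.
    """
    band = band if band is not None else BandSpec(float(tfr.freqs.min()), float(tfr.freqs.max()))
    med = np.median(tfr.power, axis=(0, 3), keepdims=True)  # (1, ch, f, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fom = np.where(med > 0, tfr.power / med, 0.0)
    structure = np.ones((3, 3), dtype=int)
    events: list[BurstEvent] = []
    n_tr, n_ch = fom.shape[:2]
    for tr in range(n_tr):
        for ci in range(n_ch):
            plane = fom[tr, ci]  # (f, t)
            supra = plane >= fom_threshold
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(supra, structure=structure)
            for lab in range(1, n_lab + 1):
                ys, xs = np.nonzero(labels == lab)
                vals = plane[ys, xs]
                vmax = vals.max()
                # tie-break: earliest time, then lowest frequency
                cand = np.flatnonzero(vals == vmax)
                order = np.lexsort((ys[cand], xs[cand]))
                j = cand[order[0]]
                fi, ti = int(ys[j]), int(xs[j])
                peak_freq = float(tfr.freqs[fi])
                if not band.f_lo <= peak_freq <= band.f_hi:
                    continue
                events.append(
                    BurstEvent(
                        trial=tr,
                        channel=tfr.channel_ids[ci],
                        peak_time=float(tfr.times[ti]),
                        peak_freq=peak_freq,
                        peak_power_fom=float(vmax),
                        duration=_fwhm(plane[fi, :], tfr.times, ti),
                        freq_span=_fwhm(plane[:, ti], tfr.freqs, fi),
                    )
                )
    return events


def summarize_bursts(events: list[BurstEvent], trial_condition: np.ndarray,
                     window_len: float, subject_id: str = "s00",
                     channel: str | None = None) -> list[BurstSummary]:
    """Per-condition burst rate (per window and per second) and mean peak
    frequency.

    Trials without events contribute to the rate denominator but not to the
    frequency mean; a condition with no events at all gets
    ``mean_peak_freq = NaN`` (flagged via ``BurstSummary.defined``).
    """
    if window_len <= 0:
        raise ValueError("summarize_bursts: window_len must be > 0")
    trial_condition = np.asarray(trial_condition, dtype=str)
    use = [e for e in events if channel is None or e.channel == channel]
    out = []
    for cond in sorted(set(trial_condition.tolist())):
        trials = np.flatnonzero(trial_condition == cond)
        trial_set = set(trials.tolist())
        evs = [e for e in use if e.trial in trial_set]
        n_ev = len(evs)
        rate = n_ev / len(trials) if len(trials) else np.nan
        out.append(
            BurstSummary(
                subject_id=subject_id,
                condition=cond,
                n_trials=len(trials),
                n_events=n_ev,
                mean_rate=rate,
                rate_per_s=rate / window_len,
                mean_peak_freq=float(np.mean([e.peak_freq for e in evs])) if n_ev else np.nan,
            )
        )
    return out


def burst_contrasts(summaries: list[list[BurstSummary]]) -> dict:
    """Group-level tests on per-subject burst summaries.

    ``summaries`` holds one [BurstSummary per condition] pair per subject.
    Returns, per condition, the one-tailed paired t of rates vs zero, and
    the two-tailed paired t contrasting mean peak frequencies between the
    two conditions; subjects with an undefined frequency mean in either
    condition are excluded pairwise (counted in ``n_excluded``).
    """
    if len(summaries) < 2:
        raise ValueError("burst_contrasts: need >= 2 subjects")
    conds = sorted({s.condition for pair in summaries for s in pair})
    if len(conds) != 2:
        raise ValueError(f"burst_contrasts: need exactly two conditions, got {conds}")

    def _get(pair, cond):
        for s in pair:
            if s.condition == cond:
                return s
        return None

    res: dict = {"conditions": conds, "rate_vs_zero": {}, "n_excluded": 0}
    for cond in conds:
        rates = np.asarray([_get(p, cond).mean_rate for p in summaries if _get(p, cond)])
        t, p = sps.ttest_1samp(rates, 0.0, alternative="greater")
        res["rate_vs_zero"][cond] = dict(
            t=float(t), df=len(rates) - 1, p=float(p),
            mean=float(rates.mean()), sd=float(rates.std(ddof=1)),
        )
    fa, fb, n_excluded = [], [], 0
    for pair in summaries:
        a, b = _get(pair, conds[0]), _get(pair, conds[1])
        if a is None or b is None or not (a.defined and b.defined):
            n_excluded += 1
            continue
        fa.append(a.mean_peak_freq)
        fb.append(b.mean_peak_freq)
    res["n_excluded"] = n_excluded
    if len(fa) >= 2:
        diffs = np.asarray(fb) - np.asarray(fa)
        if np.allclose(diffs.std(ddof=1), 0) and np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(fb, fa)
        res["freq_contrast"] = dict(
            t=float(t), df=len(fa) - 1, p=float(p),
            mean_diff=float(np.mean(diffs)),
            mean_abs_diff=float(np.mean(np.abs(diffs))),
            n_positive=int((diffs > 0).sum()),
            n_negative=int((diffs < 0).sum()),
        )
    else:
        res["freq_contrast"] = None
    return res
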