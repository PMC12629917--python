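"""Spectral power: multitaper PSD, IRASA fractal/oscillatory separation,
and the group-level power contrast.

Multitaper estimates use DPSS tapers with a chosen half-bandwidth
(``smoothing``) and zero-padding to a fixed length so that the frequency
grid step is 1/pad_to.  IRASA separates the spectrum of a signal into a
fractal (aperiodic, 1/f-like) component — the median over resampling
factors h of the geometric mean of the PSDs of the h- and 1/h-resampled
signal — and an oscillatory residual (original PSD minus fractal):
resampling by h shifts an oscillatory peak to f·h while leaving a power-law
spectrum's shape invariant, so the geometric-mean/median operation erases
peaks and retains the power law.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import BandSpec, EpochSet, NeighborGraph
from .stats import ClusterResult, StatsParams, cluster_permutation_test

__all__ = ["SpectrumSet", "multitaper_psd", "irasa_decompose", "power_contrast", "fit_loglog_slope"]

#: default IRASA resampling factors (1.1 .. 1.9 step 0.05)
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.95, 0.05), 2))


@dataclass
class SpectrumSet:
    """Power per (unit, channel, frequency).

    ``values`` has shape (n_units, n_channels, n_freqs) where a unit is a
    trial or a subject average; power is amplitude²/Hz in input units.
    Oscillatory IRASA residuals may be negative; other methods are >= 0.
    """

    values: np.ndarray
    freqs: np.ndarray
    method: str  # multitaper | irasa_fractal | irasa_oscillatory
    channel_ids: list
    unit: str = "trial"  # trial | subject-average
    smoothing: float | None = None
    subject_id: str = "s00"

    def average_trials(self) -> "SpectrumSet":
        return SpectrumSet(
            values=self.values.mean(axis=0, keepdims=True),
            freqs=self.freqs.copy(),
            method=self.method,
            channel_ids=list(self.channel_ids),
            unit="subject-average",
            smoothing=self.smoothing,
            subject_id=self.subject_id,
        )

    def restrict(self, fmin: float, fmax: float) -> "SpectrumSet":
        sel = (self.freqs >= fmin) & (self.freqs <= fmax)
        return SpectrumSet(
            values=self.values[:, :, sel].copy(),
            freqs=self.freqs[sel].copy(),
            method=self.method,
            channel_ids=list(self.channel_ids),
            unit=self.unit,
            smoothing=self.smoothing,
            subject_id=self.subject_id,
        )


def multitaper_psd(epochs: EpochSet, fmin: float = 8.0, fmax: float = 38.0,
                   smoothing: float = 2.0, pad_to: float = 4.0) -> SpectrumSet:
    """Per-trial multitaper PSD with ±``smoothing`` Hz spectral smoothing.

    The number of DPSS tapers is floor(2·smoothing·T) − 1 with T the true
    (unpadded) window length; zero-padding to ``pad_to`` seconds sets the
    grid step to 1/pad_to.  One-sided density scaling: for white noise the
    integral of the PSD over frequency matches the signal variance.
    """
    T = epochs.n_samples / epochs.fs
    if pad_to < T:
        raise ValueError(f"multitaper_psd: pad_to={pad_to} s shorter than window {T} s")
    n_tapers = int(np.floor(2.0 * smoothing * T)) - 1
    if n_tapers < 1:
        raise ValueError(
            f"multitaper_psd: smoothing={smoothing} Hz admits no taper for a {T} s "
            f"window; need smoothing > {1.0 / T:.3f} Hz"
        )
    nw = smoothing * T
    tapers = signal.windows.dpss(epochs.n_samples, NW=nw, Kmax=n_tapers)  # (K, n)
    n_fft = int(round(pad_to * epochs.fs))
    x = epochs.data.astype(np.float64)
    x = x - x.mean(axis=-1, keepdims=True)  # remove DC so padding cannot leak it
    # (trials, channels, K, n) tapered copies -> rFFT over padded length
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, n=n_fft, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=2) * (2.0 / epochs.fs)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / epochs.fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    return SpectrumSet(
        values=psd[:, :, sel],
        freqs=freqs[sel],
        method="multitaper",
        channel_ids=list(epochs.channel_ids),
        unit="trial",
        smoothing=smoothing,
        subject_id=epochs.subject_id,
    )


def _hann_psd(x: np.ndarray, fs: float, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    """One-segment Hann-tapered periodogram along the last axis."""
    n = x.shape[-1]
    win = np.hanning(n)
    xw = (x - x.mean(axis=-1, keepdims=True)) * win
    spec = np.fft.rfft(xw, n=n_fft, axis=-1)
    scale = 2.0 / (fs * (win ** 2).sum())
    return np.fft.rfftfreq(n_fft, d=1.0 / fs), (np.abs(spec) ** 2) * scale


def irasa_decompose(epochs: EpochSet, hset=DEFAULT_HSET,
                    fband: BandSpec | None = None) -> tuple[SpectrumSet, SpectrumSet]:
    """Split per-trial spectra into fractal and oscillatory components.

    For each resampling factor h, the signal is resampled by h and by 1/h
    (polyphase rational resampling), both PSDs are interpolated back to the
    original frequency grid and combined by geometric mean; the fractal
    component is the median across the h set, and the oscillatory component
    is the original (Hann periodogram) PSD minus the fractal, so
    fractal + oscillatory reproduces the original PSD exactly.  Both outputs
    are restricted to ``fband`` (defaults to the 13–35 Hz beta band).

    Per-trial periodograms are averaged within the subject *before* the
    geometric mean: the geometric mean of two single-periodogram estimates
    (chi-squared with 2 dof) is biased low by a factor of about pi/4, which
    would leave a spurious positive oscillatory residual on purely fractal
    input; trial-averaging first removes that bias.  The returned spectra
    therefore have one unit ("subject-average") per channel.
    """
    fband = fband if fband is not None else BandSpec(13.0, 35.0)
    if any(h <= 1 for h in hset):
        raise ValueError("irasa_decompose: all resampling factors must be > 1")
    x = epochs.data.astype(np.float64)
    n = epochs.n_samples
    hmax = max(hset)
    if int(n / hmax) < 32:
        raise ValueError("irasa_decompose: signal too short for the largest resampling factor")
    n_fft = n
    freqs, psd_trials = _hann_psd(x, epochs.fs, n_fft)
    psd = psd_trials.mean(axis=0, keepdims=True)  # (1, channels, freqs)

    geo_means = np.empty((len(hset),) + psd.shape)
    for i, h in enumerate(hset):
        frac = Fraction(h).limit_denominator(100)
        up = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        down = signal.resample_poly(x, frac.denominator, frac.numerator, axis=-1)
        f_up, p_up = _hann_psd(up, epochs.fs, up.shape[-1])
        f_dn, p_dn = _hann_psd(down, epochs.fs, down.shape[-1])
        if not (np.all(np.isfinite(p_up)) and np.all(np.isfinite(p_dn))):
            raise ValueError(f"irasa_decompose: non-finite resampled spectrum at h={h}")
        p_up_i = _interp_last(freqs, f_up, p_up.mean(axis=0, keepdims=True))
        p_dn_i = _interp_last(freqs, f_dn, p_dn.mean(axis=0, keepdims=True))
        geo_means[i] = np.sqrt(p_up_i * p_dn_i)
    fractal = np.median(geo_means, axis=0)
    oscillatory = psd - fractal

    common = dict(freqs=freqs, channel_ids=list(epochs.channel_ids),
                  unit="subject-average", subject_id=epochs.subject_id)
    frac_set = SpectrumSet(values=fractal, method="irasa_fractal", **common)
    osc_set = SpectrumSet(values=oscillatory, method="irasa_oscillatory", **common)
    return (frac_set.restrict(fband.f_lo, fband.f_hi),
            osc_set.restrict(fband.f_lo, fband.f_hi))


def _interp_last(xq: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """np.interp applied along the last axis of y."""
    flat = y.reshape(-1, y.shape[-1])
    out = np.empty((flat.shape[0], len(xq)))
    for i in range(flat.shape[0]):
        out[i] = np.interp(xq, x, flat[i])
    return out.reshape(y.shape[:-1] + (len(xq),))


def fit_loglog_slope(spectrum: SpectrumSet, fmin: float, fmax: float) -> float:
    """Least-squares slope of log power vs log frequency, trial/channel-averaged."""
    sel = (spectrum.freqs >= fmin) & (spectrum.freqs <= fmax) & (spectrum.freqs > 0)
    p = spectrum.values.mean(axis=(0, 1))[sel]
    f = spectrum.freqs[sel]
    good = p > 0
    coef = np.polyfit(np.log10(f[good]), np.log10(p[good]), 1)
    return float(coef[0])


def power_contrast(specA: list[SpectrumSet], specB: list[SpectrumSet],
                   graph: NeighborGraph | None = None,
                   params: StatsParams | None = None) -> ClusterResult:
    """Group cluster-permutation contrast of per-subject average spectra.

    ``specA``/``specB`` are per-subject SpectrumSets on identical frequency
    grids and channel orders; clustering runs over frequencies × neighbor
    channels.
    """
    if len(specA) != len(specB) or len(specA) < 2:
        raise ValueError("power_contrast: need matched per-subject spectra, >= 2 subjects")
    ref = specA[0]
    for s in list(specA) + list(specB):
        if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("power_contrast: frequency grid mismatch")
        if s.channel_ids != ref.channel_ids:
            raise ValueError("power_contrast: channel order mismatch")
    A = np.stack([s.values.mean(axis=0) for s in specA])
    B = np.stack([s.values.mean(axis=0) for s in specB])
    return cluster_permutation_test(A, B, graph=graph, params=params,
                                    channel_ids=ref.channel_ids, bins=ref.freqs,
                                    bin_unit="Hz")
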