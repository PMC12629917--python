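"""Single-trial instantaneous frequency within a band.

The estimator is the classic frequency-sliding chain: zero-phase FIR
bandpass, Hilbert transform, unwrapped phase, temporal derivative scaled by
fs/2π, then a cascade of ten median filters with kernel widths spanning
sub-cycle to multi-cycle smoothing; the final estimate at each sample is the
pointwise median across the ten filtered series.  Median smoothing removes
the spike artifacts that phase slips produce in the raw derivative while
preserving genuine step changes in frequency.

Edge samples contaminated by the filter transient or the largest median
kernel are excluded through a per-series validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal

from .core import BandSpec, EpochSet, ValidationError

__all__ = ["IFSeries", "bandpass", "instantaneous_frequency", "subject_condition_if"]


@dataclass
class IFSeries:
    """Per-trial, per-channel instantaneous-frequency time course.

    ``ifreq`` has shape (n_trials, n_channels, n_samples) in Hz;
    ``valid_mask`` is a per-sample boolean (shared across trials except where
    zero-amplitude spans were masked) excluding edge transients.
    """

    ifreq: np.ndarray
    valid_mask: np.ndarray
    band: BandSpec
    fs: float
    time: np.ndarray
    trial_condition: np.ndarray
    trial_correct: np.ndarray
    channel_ids: list
    subject_id: str = "s00"

    @property
    def n_trials(self) -> int:
        return self.ifreq.shape[0]


def design_bandpass(band: BandSpec, fs: float) -> np.ndarray:
    """Hamming-window FIR bandpass taps for zero-phase filtering.

    The transition width is 0.6·f_lo (so a tone one octave below the band is
    attenuated by >40 dB after forward-backward filtering) and the length is
    the usual 3.3·fs/Δf Hamming rule, rounded up to an odd tap count.
    """
    band.check_against(fs)
    transition = 0.6 * band.f_lo
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    return signal.firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs)


def bandpass(epochs: EpochSet, band: BandSpec) -> EpochSet:
    """Zero-phase (forward-backward) FIR bandpass of every trial/channel."""
    taps = design_bandpass(band, epochs.fs)
    min_len = 3 * (len(taps) - 1) // 2 + 1
    if epochs.n_samples < min_len:
        raise ValueError(
            f"bandpass: epoch has {epochs.n_samples} samples; needs >= {min_len} "
            f"for a {len(taps)}-tap zero-phase filter at fs={epochs.fs}"
        )
    out = epochs.copy()
    filtered = signal.filtfilt(taps, [1.0], epochs.data.astype(np.float64),
                               axis=-1, padlen=min_len - 1)
    out.data = filtered.astype(np.float32)
    return out


@njit(cache=False)
def _moving_median(x, k, out):  # pragma: no cover - exercised via wrapper
    """Sliding-window median along the last axis, edge-replicated.

    Maintains a sorted window with binary-search insertion; equivalent to
    scipy.ndimage.median_filter(size=(1, k), mode='nearest') but ~10x faster
    for the kernel sizes used here.
    """
    rows, n = x.shape
    h = k // 2
    win = np.empty(k, x.dtype)
    for r in range(rows):
        for j in range(k):
            idx = j - h
            if idx < 0:
                idx = 0
            win[j] = x[r, idx]
        win.sort()
        out[r, 0] = win[h]
        for i in range(1, n):
            old_idx = i - 1 - h
            if old_idx < 0:
                old_idx = 0
            new_idx = i + h
            if new_idx >= n:
                new_idx = n - 1
            old = x[r, old_idx]
            new = x[r, new_idx]
            if old != new:
                lo, hi = 0, k - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if win[mid] < old:
                        lo = mid + 1
                    else:
                        hi = mid
                pos = lo
                if new > old:
                    while pos + 1 < k and win[pos + 1] < new:
                        win[pos] = win[pos + 1]
                        pos += 1
                    win[pos] = new
                else:
                    while pos - 1 >= 0 and win[pos - 1] > new:
                        win[pos] = win[pos - 1]
                        pos -= 1
                    win[pos] = new
            out[r, i] = win[h]


def median_filter_rows(x: np.ndarray, k: int) -> np.ndarray:
    """Moving median of each row of a 2-d array (odd kernel ``k``)."""
    if k % 2 == 0:
        raise ValueError("median_filter_rows: kernel must be odd")
    x = np.ascontiguousarray(x, dtype=np.float64)
    out = np.empty_like(x)
    if k == 1:
        out[:] = x
    else:
        _moving_median(x, k, out)
    return out


def median_kernels(fs: float, n_filters: int, kernel_range_ms: tuple[float, float]) -> list[int]:
    """Kernel widths in samples: ``n_filters`` evenly spaced over the range, odd."""
    lo, hi = kernel_range_ms
    widths_ms = np.linspace(lo, hi, n_filters)
    return [max(int(round(w * fs / 1000.0)) | 1, 1) for w in widths_ms]


def instantaneous_frequency(
    epochs: EpochSet,
    band: BandSpec = BandSpec(13.0, 35.0),
    n_filters: int = 10,
    kernel_range_ms: tuple[float, float] = (10.0, 400.0),
    prefiltered: bool = False,
) -> IFSeries:
    """Estimate the instantaneous frequency of every trial and channel.

    The raw estimate is the central-difference derivative of the unwrapped
    analytic phase, scaled to Hz; it is then passed through ``n_filters``
    median filters with kernels spanning ``kernel_range_ms`` and the final
    value at each sample is the median across the filtered versions.

    Samples within the bandpass transient plus the largest kernel half-width
    of either epoch edge are marked invalid, as are spans where the analytic
    amplitude collapses below 1e-12 of the trial RMS (phase undefined).
    """
    filtered = epochs if prefiltered else bandpass(epochs, band)
    x = filtered.data.astype(np.float64)
    analytic = signal.hilbert(x, axis=-1)
    phase = np.unwrap(np.angle(analytic), axis=-1)
    raw_if = np.gradient(phase, axis=-1) * (epochs.fs / (2.0 * np.pi))

    kernels = median_kernels(epochs.fs, n_filters, kernel_range_ms)
    n_tr, n_ch, n_s = raw_if.shape
    flat = raw_if.reshape(n_tr * n_ch, n_s)
    stack = np.empty((len(kernels), n_tr * n_ch, n_s))
    for i, k in enumerate(kernels):
        stack[i] = median_filter_rows(flat, k)
    ifreq = np.median(stack, axis=0).reshape(n_tr, n_ch, n_s)

    taps = design_bandpass(band, epochs.fs)
    edge = (len(taps) - 1) // 2 + max(kernels) // 2
    valid = np.ones(n_s, dtype=bool)
    valid[: min(edge, n_s)] = False
    valid[max(n_s - edge, 0):] = False
    mask = np.broadcast_to(valid, ifreq.shape).copy()

    amp = np.abs(analytic)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    mask &= amp > 1e-12 * np.maximum(rms, np.finfo(float).tiny)

    return IFSeries(
        ifreq=ifreq,
        valid_mask=mask,
        band=band,
        fs=epochs.fs,
        time=epochs.time.copy(),
        trial_condition=epochs.trial_condition.copy(),
        trial_correct=epochs.trial_correct.copy(),
        channel_ids=list(epochs.channel_ids),
        subject_id=epochs.subject_id,
    )


def subject_condition_if(
    ifs: IFSeries, correct_only: bool = True
) -> dict:
    """Per-condition mean IF time courses and the subject-level difference.

    Returns a dict with ``conditions`` (sorted label pair), ``mean_if`` of
    shape (2, n_channels, n_samples) — the trial means per condition —
    ``diff`` (condition[1] − condition[0]), a ``valid_mask`` per
    (channel, sample), plus window-average ``signed_diff`` and ``abs_diff``
    per channel for report summaries.

    Raises ``ValueError`` naming any condition left empty after the
    ``correct_only`` filter.
    """
    sel = ifs.trial_correct if correct_only else np.ones(ifs.n_trials, dtype=bool)
    labels = sorted(set(ifs.trial_condition.tolist()))
    if len(labels) != 2:
        raise ValueError(f"subject_condition_if: need exactly two conditions, got {labels}")
    means = []
    for lab in labels:
        pick = sel & (ifs.trial_condition == lab)
        if not pick.any():
            raise ValueError(f"subject_condition_if: condition {lab!r} empty after filtering")
        # masked per-trial average: invalid samples excluded per trial
        m = np.ma.masked_array(ifs.ifreq[pick], mask=~ifs.valid_mask[pick])
        means.append(np.ma.mean(m, axis=0))
    mean_if = np.ma.stack(means)
    diff = mean_if[1] - mean_if[0]
    sample_valid = ~np.ma.getmaskarray(diff)  # (n_channels, n_samples)
    diff_filled = np.ma.filled(diff, 0.0)
    win = np.ma.mean(diff, axis=-1)
    return dict(
        conditions=labels,
        mean_if=np.ma.filled(mean_if, np.nan),
        diff=diff_filled,
        valid_mask=sample_valid,
        signed_diff=np.ma.filled(win, np.nan),
        abs_diff=np.ma.filled(np.ma.mean(np.ma.abs(diff), axis=-1), np.nan),
    )
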