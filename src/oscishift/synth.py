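"""Synthetic cohorts of epoched data with a planted frequency-shift effect.

The generator emulates the statistical structure the analysis chain assumes:
a 1/f (fractal) background, beta-band oscillations — sustained or as
transient Hann-windowed bursts — whose center frequency differs between two
decision outcomes by a small per-subject signed amount, oscillatory power
differences between the decision and baseline windows, and a cohort in which
a configurable fraction of subjects carries the shift with positive sign.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import EpochSet, NeighborGraph, ValidationError

__all__ = [
    "SimConfig",
    "EventLog",
    "default_neighbor_graph",
    "make_fractal_noise",
    "inject_oscillation",
    "simulate_subject",
    "simulate_cohort",
]

#: the four prefrontal regions of interest used as default channels
DEFAULT_CHANNELS = ("L_dlPFC", "L_vmPFC", "R_dlPFC", "R_vmPFC")


def default_neighbor_graph(channel_ids=DEFAULT_CHANNELS) -> NeighborGraph:
    """Same-hemisphere adjacency: each source has exactly one neighbor."""
    edges = set()
    for hemi in ("L", "R"):
        hemichans = [c for c in channel_ids if c.startswith(hemi + "_")]
        for a, b in zip(hemichans[:-1], hemichans[1:]):
            edges.add(frozenset((a, b)))
    return NeighborGraph(channel_ids=list(channel_ids), edges=edges)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the decision-delay recordings the pipeline targets:
    250 Hz sampling, a 1.5 s decision window and equally long pre-stimulus
    baseline, four prefrontal sources, 100 trials per decision outcome,
    a 1/f background with exponent 1, beta oscillations centered at 21 Hz
    with 0.5 Hz trial-to-trial center jitter and amplitude calibrated so the
    instantaneous-frequency pipeline recovers a planted shift with little
    attenuation at cohort scale,
    a condition-dependent center-frequency shift of 0.3 Hz carried by the
    left-hemisphere sources, ~2.9 bursts per decision window in burst mode,
    oscillatory amplitude suppressed in the decision window relative to
    baseline, and 17/24 of subjects sharing the positive shift sign.
    """

    fs: float = 250.0
    n_channels: int = 4
    n_trials_per_condition: int = 100
    window_len: float = 1.5
    baseline_len: float = 1.5
    fractal_exponent: float = 1.0
    fractal_amplitude: float = 1.0
    osc_mode: str = "bursts"  # "sustained" | "bursts"
    burst_rate: float = 1.9  # events/s -> ~2.9 per 1.5 s window
    burst_len_cycles: float = 5.0
    osc_amplitude: float = 2.0
    f_center_A: float = 21.0
    delta_f: float = 0.3
    freq_jitter_sd: float = 0.5
    positive_sign_fraction: float = 17 / 24
    decision_power_scale: float = 0.75
    effect_channels: tuple = ("L_dlPFC", "L_vmPFC")
    channel_ids: tuple = DEFAULT_CHANNELS
    condition_names: tuple = ("A", "B")
    unit: str = "arbitrary"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs <= 2 * (self.f_center_A + abs(self.delta_f) + 3 * self.freq_jitter_sd):
            raise ValidationError("SimConfig: fs too low for the configured oscillation band")
        if not 0 <= self.positive_sign_fraction <= 1:
            raise ValidationError("SimConfig: positive_sign_fraction outside [0, 1]")
        if self.burst_rate < 0:
            raise ValidationError("SimConfig: burst_rate must be >= 0")
        if self.osc_amplitude < 0 or self.fractal_amplitude < 0:
            raise ValidationError("SimConfig: amplitudes must be >= 0")
        if self.osc_mode not in ("sustained", "bursts"):
            raise ValidationError(f"SimConfig: unknown osc_mode {self.osc_mode!r}")
        if len(self.channel_ids) != self.n_channels:
            raise ValidationError("SimConfig: channel_ids length != n_channels")
        unknown = set(self.effect_channels) - set(self.channel_ids)
        if unknown:
            raise ValidationError(f"SimConfig: effect_channels {sorted(unknown)} not in channel_ids")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("effect_channels", "channel_ids", "condition_names"):
            d[k] = list(d[k])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"SimConfig: unknown keys {sorted(unknown)}")
        for k in ("effect_channels", "channel_ids", "condition_names"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class EventLog:
    """Ground-truth record of injected oscillatory events.

    Each record is ``(trial, channel, onset_s, freq_hz, amplitude,
    duration_s, truncated)``; ``truncated`` flags events clipped at the
    window edge.
    """

    records: list = field(default_factory=list)

    def add(self, trial, channel, onset, freq, amplitude, duration, truncated=False):
        self.records.append(
            dict(trial=int(trial), channel=str(channel), onset_s=float(onset),
                 freq_hz=float(freq), amplitude=float(amplitude),
                 duration_s=float(duration), truncated=bool(truncated))
        )

    def __len__(self) -> int:
        return len(self.records)

    def extend(self, other: "EventLog") -> None:
        self.records.extend(other.records)

    def to_tsv(self) -> str:
        header = "trial\tchannel\tonset_s\tfreq_hz\tamplitude\tduration_s\ttruncated"
        lines = [header]
        for r in self.records:
            lines.append(
                f"{r['trial']}\t{r['channel']}\t{r['onset_s']:.6f}\t{r['freq_hz']:.6f}"
                f"\t{r['amplitude']:.6f}\t{r['duration_s']:.6f}\t{int(r['truncated'])}"
            )
        return "\n".join(lines) + "\n"


def _power_law_noise(rng: np.random.Generator, shape, n_samples: int, fs: float,
                     exponent: float, amplitude: float) -> np.ndarray:
    """White Gaussian noise spectrally shaped to PSD ∝ f^(−exponent).

    The shaping gain is normalized to unit expected variance so ``amplitude``
    is the expected RMS of each trace; the DC bin is zeroed by construction.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    # unit-variance normalization (DC excluded); Nyquist/DC weights ~ n large
    norm = np.sqrt(np.mean(gain[1:] ** 2)) if n_samples > 2 else 1.0
    if norm > 0:
        gain = gain / norm
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    return amplitude * shaped


def make_fractal_noise(n_trials: int, n_channels: int, n_samples: int, fs: float,
                       exponent: float, amplitude: float = 1.0, seed: int = 0,
                       cfg: SimConfig | None = None) -> EpochSet:
    """Independent 1/f^χ Gaussian noise realizations as an :class:`EpochSet`.

    Trials are split evenly over the two condition labels ("A" first).
    """
    if n_samples < 64:
        raise ValueError("make_fractal_noise: need n_samples >= 64")
    if exponent < 0:
        raise ValueError("make_fractal_noise: need exponent >= 0")
    rng = np.random.default_rng(seed)
    data = _power_law_noise(rng, (n_trials, n_channels), n_samples, fs, exponent, amplitude)
    names = cfg.condition_names if cfg is not None else ("A", "B")
    cond = np.asarray([names[0] if i < (n_trials + 1) // 2 else names[1] for i in range(n_trials)])
    chans = (list(cfg.channel_ids) if cfg is not None and len(cfg.channel_ids) == n_channels
             else [f"ch{i:02d}" for i in range(n_channels)])
    return EpochSet(
        data=data,
        fs=fs,
        time=np.arange(n_samples) / fs,
        channel_ids=chans,
        trial_condition=cond,
        trial_correct=np.ones(n_trials, dtype=bool),
        window_tag="decision",
        unit=cfg.unit if cfg is not None else "arbitrary",
    )


def inject_oscillation(epochs: EpochSet, cfg: SimConfig, condition_freq: float,
                       seed: int = 0, trials: np.ndarray | None = None,
                       channels: tuple | None = None,
                       amplitude: float | None = None) -> tuple[EpochSet, EventLog]:
    """Add a sustained oscillation or Poisson bursts on selected channels.

    Sustained mode adds a full-window sinusoid with per-trial frequency
    ~ Normal(condition_freq, freq_jitter_sd) and random phase per
    trial/channel.  Burst mode adds Poisson(rate · window) Hann-windowed
    events per trial/channel, each with its own frequency draw; an event
    extending past the window is truncated and flagged in the log.
    Channels outside the selection are untouched; the input is not modified.
    """
    if not 0 < condition_freq < epochs.fs / 2:
        raise ValueError("inject_oscillation: condition_freq outside (0, fs/2)")
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    log = EventLog()
    channels = cfg.effect_channels if channels is None else channels
    ch_idx = [epochs.channel_index(c) for c in channels]
    trial_idx = np.arange(epochs.n_trials) if trials is None else np.asarray(trials)
    amp = cfg.osc_amplitude if amplitude is None else amplitude
    t = epochs.time
    window_len = epochs.n_samples / epochs.fs
    add = np.zeros((epochs.n_trials, epochs.n_channels, epochs.n_samples))

    if cfg.osc_mode == "sustained":
        freqs = rng.normal(condition_freq, cfg.freq_jitter_sd, size=len(trial_idx))
        for i, tr in enumerate(trial_idx):
            for ci in ch_idx:
                phase = rng.uniform(0, 2 * np.pi)
                add[tr, ci] = amp * np.cos(2 * np.pi * freqs[i] * t + phase)
                log.add(tr, epochs.channel_ids[ci], t[0], freqs[i], amp, window_len)
    else:  # bursts
        lam = cfg.burst_rate * window_len
        for tr in trial_idx:
            for ci in ch_idx:
                n_events = rng.poisson(lam)
                for _ in range(n_events):
                    f = rng.normal(condition_freq, cfg.freq_jitter_sd)
                    f = max(f, 1.0)
                    dur = cfg.burst_len_cycles / f
                    onset = rng.uniform(t[0], t[0] + window_len)
                    phase = rng.uniform(0, 2 * np.pi)
                    i0 = int(round((onset - t[0]) * epochs.fs))
                    n_ev = int(round(dur * epochs.fs))
                    truncated = i0 + n_ev > epochs.n_samples
                    i1 = min(i0 + n_ev, epochs.n_samples)
                    if n_ev >= 2 and i1 > i0:
                        tt = t[i0:i1] - onset
                        env = np.hanning(n_ev)[: i1 - i0]
                        add[tr, ci, i0:i1] += amp * env * np.cos(2 * np.pi * f * tt + phase)
                    log.add(tr, epochs.channel_ids[ci], onset, f, amp,
                            (i1 - i0) / epochs.fs, truncated)
    out.data = (out.data.astype(np.float64) + add).astype(np.float32)
    return out, log


def _one_window(cfg: SimConfig, rng_seeds, subject_sign: int, subject_id: str,
                window_tag: str, window_len: float, amp: float,
                shifted: bool) -> tuple[EpochSet, EventLog]:
    """Noise plus oscillation for one window; shift applied only if ``shifted``."""
    n_samples = int(round(window_len * cfg.fs))
    n_tr = cfg.n_trials_per_condition
    noise = make_fractal_noise(
        2 * n_tr, cfg.n_channels, n_samples, cfg.fs, cfg.fractal_exponent,
        cfg.fractal_amplitude, seed=rng_seeds[0], cfg=cfg,
    )
    a_name, b_name = cfg.condition_names
    cond = np.asarray([a_name] * n_tr + [b_name] * n_tr)
    noise.trial_condition = cond
    noise.subject_id = subject_id
    noise.window_tag = window_tag

    trials_a = np.arange(n_tr)
    trials_b = np.arange(n_tr, 2 * n_tr)
    f_a = cfg.f_center_A
    f_b = cfg.f_center_A + (subject_sign * cfg.delta_f if shifted else 0.0)
    log = EventLog()
    out = noise
    null_channels = tuple(c for c in cfg.channel_ids if c not in cfg.effect_channels)
    if cfg.osc_amplitude > 0:
        out, l1 = inject_oscillation(out, cfg, f_a, seed=rng_seeds[1],
                                     trials=trials_a, channels=cfg.effect_channels,
                                     amplitude=amp)
        out, l2 = inject_oscillation(out, cfg, f_b, seed=rng_seeds[2],
                                     trials=trials_b, channels=cfg.effect_channels,
                                     amplitude=amp)
        log.extend(l1)
        log.extend(l2)
        if null_channels:
            # non-effect channels oscillate at the unshifted center in both conditions
            out, l3 = inject_oscillation(out, cfg, f_a, seed=rng_seeds[3],
                                         channels=null_channels, amplitude=amp)
            log.extend(l3)
    return out, log


def simulate_subject(cfg: SimConfig, subject_sign: int = 1, seed: int = 0,
                     subject_id: str | None = None) -> tuple[EpochSet, EpochSet, EventLog]:
    """One subject's decision and baseline windows plus the event log.

    The decision window carries the condition-dependent shift (condition A at
    ``f_center_A``, condition B at ``f_center_A + subject_sign * delta_f``)
    on the effect channels only; the baseline window has no
    condition-dependent frequency difference, and its oscillatory amplitude
    is ``osc_amplitude / decision_power_scale``.
    """
    if subject_sign not in (-1, 1):
        raise ValueError("simulate_subject: subject_sign must be +1 or -1")
    cfg.validate()
    subject_id = subject_id if subject_id is not None else f"s{seed:04d}"
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    decision, log = _one_window(
        cfg, seeds[:4], subject_sign, subject_id, "decision", cfg.window_len,
        amp=cfg.osc_amplitude, shifted=True,
    )
    baseline, _ = _one_window(
        cfg, seeds[4:], subject_sign, subject_id, "baseline", cfg.baseline_len,
        amp=cfg.osc_amplitude / cfg.decision_power_scale, shifted=False,
    )
    baseline.time = baseline.time - cfg.baseline_len  # baseline precedes onset
    return decision, baseline, log


def simulate_cohort(cfg: SimConfig, n_subjects: int, seed: int | None = None) -> list[dict]:
    """Simulate ``n_subjects`` subjects with an exact-count sign assignment.

    Exactly ``round(positive_sign_fraction * n_subjects)`` subjects receive
    ``subject_sign = +1``; the assignment order is shuffled by the master
    seed, and per-subject seeds are spawned deterministically from it.
    Returns a list of dicts with keys ``subject_id, sign, decision, baseline,
    events``.
    """
    if n_subjects < 2:
        raise ValueError("simulate_cohort: need n_subjects >= 2")
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(master)
    n_pos = int(round(cfg.positive_sign_fraction * n_subjects))
    signs = np.asarray([1] * n_pos + [-1] * (n_subjects - n_pos))
    rng.shuffle(signs)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in np.random.SeedSequence(master).spawn(n_subjects)]
    out = []
    for i in range(n_subjects):
        sid = f"sub{i + 1:02d}"
        dec, base, log = simulate_subject(cfg, int(signs[i]), seed=sub_seeds[i], subject_id=sid)
        out.append(dict(subject_id=sid, sign=int(signs[i]), decision=dec,
                        baseline=base, events=log))
    return out
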