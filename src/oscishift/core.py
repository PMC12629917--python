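"""Core containers: epoched data, channel adjacency, and frequency bands.

An :class:`EpochSet` is the unit of exchange between every analysis stage:
a ``(n_trials, n_channels, n_samples)`` tensor with a uniform time axis,
per-trial two-level condition labels and correctness flags, and subject /
window metadata.  A :class:`NeighborGraph` holds the channel adjacency that
constrains spatial clustering, and a :class:`BandSpec` is a half-open
frequency band in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "EpochSet",
    "NeighborGraph",
    "BandSpec",
    "crop_window",
    "validate_neighbors",
]


class ValidationError(ValueError):
    """Raised when a container violates one of its documented invariants."""


_WINDOW_TAGS = ("baseline", "decision")

#: relative tolerance on time-axis uniformity
_TIME_RTOL = 1e-9


@dataclass
class EpochSet:
    """Epoched multichannel time series for one subject and one window.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitude in ``unit``.
    fs : float
        Sampling rate in Hz.
    time : ndarray, shape (n_samples,)
        Seconds relative to window onset; uniformly spaced with step 1/fs.
    channel_ids : sequence of str
        Ordered channel labels.
    trial_condition : ndarray of str, shape (n_trials,)
        Per-trial label from a two-level set.
    trial_correct : ndarray of bool, shape (n_trials,)
        Per-trial correctness flag.
    subject_id : str
    window_tag : {"baseline", "decision"}
    unit : str
        Opaque amplitude unit ("arbitrary", "V", "T", ...); never converted.
    """

    data: np.ndarray
    fs: float
    time: np.ndarray
    channel_ids: list[str]
    trial_condition: np.ndarray
    trial_correct: np.ndarray
    subject_id: str = "s00"
    window_tag: str = "decision"
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        # float32 is the container's native precision; compute stages promote
        self.data = np.asarray(self.data, dtype=np.float32)
        self.time = np.asarray(self.time, dtype=np.float64)
        self.channel_ids = [str(c) for c in self.channel_ids]
        self.trial_condition = np.asarray(self.trial_condition, dtype=str)
        self.trial_correct = np.asarray(self.trial_correct, dtype=bool)
        self.validate()

    # -- shape helpers ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels, sorted."""
        return sorted(set(self.trial_condition.tolist()))

    def validate(self) -> None:
        """Check all invariants; raise :class:`ValidationError` naming the field."""
        if self.data.ndim != 3:
            raise ValidationError(
                f"data: expected 3-d (trials, channels, samples), got ndim={self.data.ndim}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"data: non-finite value at trial {bad[0]}, channel {bad[1]}, sample {bad[2]}"
            )
        if self.fs <= 0:
            raise ValidationError(f"fs: must be positive, got {self.fs}")
        if self.time.shape != (n_samples,):
            raise ValidationError(
                f"time: length {self.time.shape} does not match n_samples={n_samples}"
            )
        if n_samples > 1:
            steps = np.diff(self.time)
            expected = 1.0 / self.fs
            if not np.allclose(steps, expected, rtol=_TIME_RTOL, atol=_TIME_RTOL * expected):
                raise ValidationError("time: axis not uniformly spaced with step 1/fs")
        if len(self.channel_ids) != n_channels:
            raise ValidationError(
                f"channel_ids: length {len(self.channel_ids)} does not match n_channels={n_channels}"
            )
        if len(set(self.channel_ids)) != n_channels:
            raise ValidationError("channel_ids: labels not unique")
        if self.trial_condition.shape != (n_trials,):
            raise ValidationError(
                f"trial_condition: length {self.trial_condition.shape[0] if self.trial_condition.ndim else 0} "
                f"does not match n_trials={n_trials}"
            )
        if self.trial_correct.shape != (n_trials,):
            raise ValidationError(
                f"trial_correct: length does not match n_trials={n_trials}"
            )
        if len(set(self.trial_condition.tolist())) > 2:
            raise ValidationError("trial_condition: more than two condition levels")
        if self.window_tag not in _WINDOW_TAGS:
            raise ValidationError(
                f"window_tag: {self.window_tag!r} not in {_WINDOW_TAGS}"
            )

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            time=self.time.copy(),
            channel_ids=list(self.channel_ids),
            trial_condition=self.trial_condition.copy(),
            trial_correct=self.trial_correct.copy(),
        )


@dataclass
class NeighborGraph:
    """Undirected channel adjacency defining spatial cluster connectivity."""

    channel_ids: list[str]
    edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.channel_ids = [str(c) for c in self.channel_ids]
        norm = set()
        for e in self.edges:
            pair = frozenset(str(x) for x in e)
            if len(pair) != 2:
                raise ValidationError(f"edges: self-pair or malformed edge {sorted(e)}")
            norm.add(pair)
        self.edges = norm
        known = set(self.channel_ids)
        for e in self.edges:
            for c in e:
                if c not in known:
                    raise ValidationError(f"edges: unknown channel {c!r}")

    def neighbors(self, channel_id: str) -> set[str]:
        return {next(iter(e - {channel_id})) for e in self.edges if channel_id in e}

    def neighbor_indices(self, channel_order: Sequence[str]) -> list[tuple[int, int]]:
        """Edges as index pairs in the given channel ordering."""
        pos = {c: i for i, c in enumerate(channel_order)}
        out = []
        for e in self.edges:
            a, b = sorted(e)
            if a in pos and b in pos:
                out.append((pos[a], pos[b]))
        return sorted(out)


@dataclass(frozen=True)
class BandSpec:
    """Frequency band [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(f"BandSpec: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def check_against(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValidationError(
                f"BandSpec: f_hi={self.f_hi} Hz not below Nyquist {fs / 2} Hz"
            )


#: default beta band used throughout
BETA_BAND = BandSpec(13.0, 35.0)


def crop_window(
    epochs: EpochSet, t0: float, t1: float, window_tag: str | None = None
) -> EpochSet:
    """Return the samples with ``t0 <= time < t1`` (half-open window).

    Metadata is preserved; ``window_tag`` may be reassigned.  Raises
    ``ValueError`` for an empty result or out-of-range bounds.
    """
    if not t0 < t1:
        raise ValueError(f"crop_window: need t0 < t1, got [{t0}, {t1})")
    eps = 0.5 / epochs.fs
    if t0 < epochs.time[0] - eps or t1 > epochs.time[-1] + 1.0 / epochs.fs + eps:
        raise ValueError(
            f"crop_window: [{t0}, {t1}) outside epoch range "
            f"[{epochs.time[0]}, {epochs.time[-1] + 1.0 / epochs.fs})"
        )
    # half-open selection on a uniform grid; tolerant to float rounding
    mask = (epochs.time >= t0 - eps) & (epochs.time < t1 - eps)
    if not mask.any():
        raise ValueError(f"crop_window: no samples in [{t0}, {t1})")
    out = replace(
        epochs,
        data=epochs.data[:, :, mask].copy(),
        time=epochs.time[mask].copy(),
        window_tag=window_tag if window_tag is not None else epochs.window_tag,
    )
    return out


def validate_neighbors(graph: NeighborGraph, epochs: EpochSet) -> tuple[bool, list[str]]:
    """Check graph/epochs consistency; returns (ok, reasons).

    True iff the graph's channel set equals the epoch set's channels and the
    graph invariants (symmetry by construction, no self-pairs, referential
    integrity) hold.
    """
    reasons: list[str] = []
    gset, eset = set(graph.channel_ids), set(epochs.channel_ids)
    if gset != eset:
        missing = sorted(eset - gset)
        extra = sorted(gset - eset)
        if missing:
            reasons.append(f"graph missing channels {missing}")
        if extra:
            reasons.append(f"graph has unknown channels {extra}")
    for e in graph.edges:
        for c in e:
            if c not in eset:
                reasons.append(f"edge references channel {c!r} absent from epochs")
    return (len(reasons) == 0, reasons)
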