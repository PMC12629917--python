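"""On-disk interchange: HDF5 epoch containers and JSON neighbor graphs.

Layout of the epochs container (one file per subject per window)::

    /data            float32, (trials, channels, samples)
    /time            float64, seconds
    /trial_condition string array
    /trial_correct   uint8
    attributes: fs, subject_id, window_tag, unit, channel_ids

Datasets are written with ``track_times=False`` so that identical content
produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import BandSpec, EpochSet, NeighborGraph, ValidationError

__all__ = ["write_epochs", "read_epochs", "write_neighbor_graph", "read_neighbor_graph",
           "write_ifseries", "read_ifseries", "FormatError"]


class FormatError(ValueError):
    """Raised when a container file does not follow the documented layout."""


_REQUIRED_DATASETS = ("data", "time", "trial_condition", "trial_correct")
_REQUIRED_ATTRS = ("fs", "subject_id", "window_tag", "unit", "channel_ids")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to ``path``; round-trips exactly.

    ``/data`` is stored as float32 (the working precision of the pipeline's
    inputs); :func:`read_epochs` returns exactly the stored float32 values.
    """
    epochs.validate()
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32), track_times=False)
        f.create_dataset("time", data=epochs.time.astype(np.float64), track_times=False)
        f.create_dataset(
            "trial_condition",
            data=np.asarray(epochs.trial_condition, dtype=object),
            dtype=str_dt,
            track_times=False,
        )
        f.create_dataset(
            "trial_correct", data=epochs.trial_correct.astype(np.uint8), track_times=False
        )
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["window_tag"] = epochs.window_tag
        f.attrs["unit"] = epochs.unit
        f.attrs["channel_ids"] = np.asarray(epochs.channel_ids, dtype=object)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`.

    Raises :class:`FormatError` listing any missing dataset or attribute, and
    :class:`~oscishift.core.ValidationError` if the stored content violates
    the container invariants (e.g. NaN samples, non-uniform time axis).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_DATASETS if k not in f]
        missing += [f"attr:{k}" for k in _REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise FormatError(f"{path}: missing required keys {missing}")
        data = np.asarray(f["data"], dtype=np.float32)
        time = np.asarray(f["time"], dtype=np.float64)
        cond = np.asarray([c.decode() if isinstance(c, bytes) else str(c) for c in f["trial_condition"][()]])
        correct = np.asarray(f["trial_correct"], dtype=bool)
        channel_ids = [
            c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_ids"]
        ]
        return EpochSet(
            data=data,
            fs=float(f.attrs["fs"]),
            time=time,
            channel_ids=channel_ids,
            trial_condition=cond,
            trial_correct=correct,
            subject_id=str(f.attrs["subject_id"]),
            window_tag=str(f.attrs["window_tag"]),
            unit=str(f.attrs["unit"]),
        )


def write_ifseries(ifs, path: str | Path) -> Path:
    """Persist an :class:`~oscishift.instafreq.IFSeries` (`/ifreq`,
    `/valid_mask`, labels and band/fs attributes) to HDF5."""
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("ifreq", data=np.asarray(ifs.ifreq, dtype=np.float64),
                         track_times=False)
        f.create_dataset("valid_mask", data=np.asarray(ifs.valid_mask, dtype=np.uint8),
                         track_times=False)
        f.create_dataset("time", data=np.asarray(ifs.time, dtype=np.float64),
                         track_times=False)
        f.create_dataset("trial_condition",
                         data=np.asarray(ifs.trial_condition, dtype=object),
                         dtype=str_dt, track_times=False)
        f.create_dataset("trial_correct", data=np.asarray(ifs.trial_correct, dtype=np.uint8),
                         track_times=False)
        f.attrs["fs"] = float(ifs.fs)
        f.attrs["band"] = [float(ifs.band.f_lo), float(ifs.band.f_hi)]
        f.attrs["subject_id"] = ifs.subject_id
        f.attrs["channel_ids"] = np.asarray(ifs.channel_ids, dtype=object)
    return path


def read_ifseries(path: str | Path):
    """Inverse of :func:`write_ifseries`."""
    from .instafreq import IFSeries

    with h5py.File(path, "r") as f:
        needed = ("ifreq", "valid_mask", "time", "trial_condition", "trial_correct")
        missing = [k for k in needed if k not in f]
        if missing:
            raise FormatError(f"{path}: missing required keys {missing}")
        lo, hi = (float(v) for v in f.attrs["band"])
        return IFSeries(
            ifreq=np.asarray(f["ifreq"], dtype=np.float64),
            valid_mask=np.asarray(f["valid_mask"], dtype=bool),
            band=BandSpec(lo, hi),
            fs=float(f.attrs["fs"]),
            time=np.asarray(f["time"], dtype=np.float64),
            trial_condition=np.asarray(
                [c.decode() if isinstance(c, bytes) else str(c)
                 for c in f["trial_condition"][()]]),
            trial_correct=np.asarray(f["trial_correct"], dtype=bool),
            channel_ids=[c.decode() if isinstance(c, bytes) else str(c)
                         for c in f.attrs["channel_ids"]],
            subject_id=str(f.attrs["subject_id"]),
        )


def write_neighbor_graph(graph: NeighborGraph, path: str | Path) -> Path:
    path = Path(path)
    edges = sorted(sorted(e) for e in graph.edges)
    payload = {"channels": list(graph.channel_ids), "edges": edges}
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def read_neighbor_graph(path: str | Path) -> NeighborGraph:
    """Read a ``{"channels": [...], "edges": [["a","b"], ...]}`` JSON file.

    Edge pairs are unordered; a pair listing an unknown channel or a channel
    with itself raises :class:`~oscishift.core.ValidationError`.
    """
    payload = json.loads(Path(path).read_text())
    if "channels" not in payload or "edges" not in payload:
        raise FormatError(f"{path}: neighbor graph needs 'channels' and 'edges'")
    return NeighborGraph(
        channel_ids=payload["channels"],
        edges={frozenset(e) for e in payload["edges"]},
    )
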