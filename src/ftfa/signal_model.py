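"""Continuous-EEG data model, event tables and cue-locked epoching.

The containers here are deliberately minimal: a :class:`Recording` is a
channels × samples matrix of amplitudes in microvolts with a sampling rate
and (optionally) 2-D scalp positions; an :class:`EventTable` is an ordered
list of (sample index, condition) pairs; an :class:`EpochSet` is the
trials × channels × samples tensor obtained by cutting fixed windows around
each event.  Epoch windows are half-open ``[tmin, tmax)`` so that the
canonical −2..4 s window at 250 Hz yields exactly 1500 samples.

Input data are assumed to be already acquisition-filtered (band-pass /
notch happen at the amplifier); no filtering is applied here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventTable",
    "EpochSet",
    "epoch_extract",
    "group_trials",
    "read_edf",
    "read_events_csv",
    "write_events_csv",
    "read_montage_csv",
    "standard_1020_montage",
]


class EpochWindowError(ValueError):
    """Epoch window is empty, inverted, or falls outside the recording."""


class LabelError(ValueError):
    """A trial label is not in the declared condition set."""


# Unit-circle head coordinates (x: left→right, y: back→front) for the common
# 10-20 positions.  Derived from the standard angular layout; adequate for
# topographic display, not for source modelling.
_STANDARD_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.46, 0.53), "Fz": (0.0, 0.50),
    "F4": (0.46, 0.53), "F8": (0.81, 0.59),
    "FC3": (-0.53, 0.28), "FCz": (0.0, 0.25), "FC4": (0.53, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP3": (-0.53, -0.28), "CPz": (0.0, -0.25), "CP4": (0.53, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.46, -0.53), "Pz": (0.0, -0.50),
    "P4": (0.46, -0.53), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


def standard_1020_montage(labels: Sequence[str] | None = None) -> dict[str, tuple[float, float]]:
    """Return built-in 10–20 scalp positions, optionally restricted to *labels*.

    Raises ``KeyError`` if a requested label has no built-in position.
    """
    if labels is None:
        return dict(_STANDARD_1020)
    return {lab: _STANDARD_1020[lab] for lab in labels}


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (10–20 system where applicable).
    montage : dict, optional
        label → (x, y) unitless head-circle coordinates.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels × samples)")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.montage is not None:
            missing = [c for c in self.channel_labels if c not in self.montage]
            if missing:
                raise ValueError(f"montage lacks positions for {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventTable:
    """Ordered cue events: sample indices plus condition labels.

    ``condition_set`` declares the finite label alphabet; it defaults to the
    sorted set of labels present.
    """

    samples: np.ndarray
    conditions: list[str]
    condition_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.conditions = [str(c) for c in self.conditions]
        if self.samples.ndim != 1 or len(self.samples) != len(self.conditions):
            raise ValueError("samples and conditions must be 1-D and equal length")
        if len(self.samples) and np.any(np.diff(self.samples) <= 0):
            raise ValueError("event sample indices must be strictly increasing")
        if not self.condition_set:
            self.condition_set = tuple(sorted(set(self.conditions)))
        bad = set(self.conditions) - set(self.condition_set)
        if bad:
            raise LabelError(f"labels {sorted(bad)} outside declared set {self.condition_set}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EpochSet:
    """Cue-locked trial tensor: trials × channels × samples (µV)."""

    data: np.ndarray
    fs: float
    tmin_s: float
    tmax_s: float
    labels: list[str]
    channel_labels: list[str]
    condition_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials × channels × samples)")
        n_expected = int(round((self.tmax_s - self.tmin_s) * self.fs))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != round((tmax-tmin)*fs) = {n_expected}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if not self.condition_set:
            self.condition_set = tuple(sorted(set(self.labels)))
        bad = set(self.labels) - set(self.condition_set)
        if bad:
            raise LabelError(f"labels {sorted(bad)} outside declared set {self.condition_set}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Seconds relative to the cue, one entry per sample (half-open)."""
        return self.tmin_s + np.arange(self.n_samples) / self.fs


def epoch_extract(
    recording: Recording,
    events: EventTable,
    tmin_s: float,
    tmax_s: float,
) -> EpochSet:
    """Cut fixed half-open windows ``[event + tmin, event + tmax)`` around each event.

    Trial *t*, channel *c*, sample *k* equals the recording sample at
    ``event_t + round(tmin_s · fs) + k``.  Every window must lie fully
    inside the recording.
    """
    if not tmax_s > tmin_s:
        raise EpochWindowError(f"invalid window: tmax ({tmax_s}) must exceed tmin ({tmin_s})")
    fs = recording.fs
    n_samp = int(round((tmax_s - tmin_s) * fs))
    if n_samp < 1:
        raise EpochWindowError("window shorter than one sample")
    offset = int(round(tmin_s * fs))
    trials = np.empty((len(events), recording.n_channels, n_samp), dtype=float)
    for t, ev in enumerate(events.samples):
        start = int(ev) + offset
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            raise EpochWindowError(
                f"event {t} at sample {int(ev)}: window [{start}, {stop}) exceeds "
                f"recording bounds [0, {recording.n_samples})"
            )
        trials[t] = recording.data[:, start:stop]
    return EpochSet(
        data=trials,
        fs=fs,
        tmin_s=tmin_s,
        tmax_s=tmax_s,
        labels=list(events.conditions),
        channel_labels=list(recording.channel_labels),
        condition_set=events.condition_set,
    )


def group_trials(epochs: EpochSet) -> dict[str, np.ndarray]:
    """Map each condition to the indices of its trials, in trial order.

    Only conditions that actually occur appear as keys; every trial index
    lands in exactly one group.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot group an empty EpochSet")
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(epochs.labels):
        if lab not in epochs.condition_set:
            raise LabelError(f"trial {idx} label {lab!r} outside declared set")
        groups.setdefault(lab, []).append(idx)
    return {lab: np.asarray(ix, dtype=np.intp) for lab, ix in groups.items()}


# ---------------------------------------------------------------------------
# File interfaces


def read_edf(path: str | Path, montage: Mapping[str, tuple[float, float]] | None = None) -> Recording:
    """Read a continuous EDF recording (channel labels from the header)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    labels = list(raw.ch_names)
    mont = dict(montage) if montage is not None else None
    return Recording(data=data, fs=float(raw.info["sfreq"]), channel_labels=labels, montage=mont)


def read_events_csv(path: str | Path, condition_set: Sequence[str] | None = None) -> EventTable:
    """Read events from a CSV with header columns ``sample,condition``."""
    df = pd.read_csv(path)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"events CSV must have a '{col}' column")
    return EventTable(
        samples=df["sample"].to_numpy(dtype=np.int64),
        conditions=[str(c) for c in df["condition"]],
        condition_set=tuple(condition_set) if condition_set else (),
    )


def write_events_csv(events: EventTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "condition"])
        for s, c in zip(events.samples, events.conditions):
            w.writerow([int(s), c])


def read_montage_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read scalp positions from a CSV with header columns ``label,x,y``."""
    df = pd.read_csv(path)
    for col in ("label", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"montage CSV must have a '{col}' column")
    return {str(r.label): (float(r.x), float(r.y)) for r in df.itertuples()}
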